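animal_id,status,sex,age_months,body_weight_kg,brain_weight_g,sampling_delay_min
1,wild_type,ewe,64,76.4,128.9,52
2,wild_type,ewe,64,86.6,132.5,41
3,wild_type,ram,70,94.4,126.1,62
4,wild_type,ram,70,74.2,123.7,50
5,wild_type,ram,70,104.0,138.6,56
6,wild_type,ram,70,104.0,143.7,63
7,transgenic,ewe,64,72.0,124.2,47
8,transgenic,ewe,64,75.6,128.2,45
9,transgenic,ewe,64,73.2,118.2,46
10,transgenic,ram,70,85.8,124.6,61
11,transgenic,ram,70,88,123.8,55
12,transgenic,ram,64,91.4,129.2,62
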