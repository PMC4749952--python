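# Methods

This note documents the statistical model behind `diffmet`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Data model and normalization

The unit of input is a raw GC-MS peak height per (animal, tissue,
technical replicate, metabolite), with one internal-standard abundance
and one dried-pellet weight per extraction (animal × tissue). The
relative abundance is `raw / (IS × pellet)`; the internal standard (an
isotope-labelled compound spiked at a fixed amount into every
extraction) corrects extraction-efficiency variation and the pellet
weight corrects the amount of starting tissue. Both normalizers enter as
one multiplicative factor per extraction, so their units are arbitrary:
on the log10 scale they contribute an additive per-extraction offset
that cancels in within-tissue group contrasts and in correlations.
Normalization is computed as a single fused expression (no intermediate
rounding), and analysis proceeds on `log10` relative abundances, which
are approximately Gaussian for this kind of data.

Missing values (empty cells) mean "not quantified" and are never
imputed. A raw abundance of exactly 0 has no defined log and is treated
as missing. Per tissue, only metabolites quantified in every
(animal, replicate) combination are retained (`filter_complete_metabolites`);
everything downstream assumes complete tables.

## Differential abundance

Per metabolite within a tissue, an OLS model
`y = μ + status + replicate_set` is fitted on replicate-level rows. The
replicate-set term is a fixed additive effect for the two derivatization
sets, which were measured sequentially and thus form a natural batch; it
is dropped when only one set is present. The transgene effect is the
transgenic-minus-wild-type least-squares-mean contrast (in this additive
coding, the status coefficient), which in a balanced design equals the
difference of raw group means.

Inference is carried out in the between-animal stratum. The two
technical replicates of one extraction share that animal's biological
deviation, so treating replicate rows as independent errors for a
between-animal contrast is pseudoreplication: in simulation it roughly
triples the nominal type-I error (0.18 at α = 0.05) and understates the
SED. When the animal grouping is supplied (the default in
`run_diffabund`), the status contrast is therefore tested on
replicate-set-adjusted animal means with df = animals − model terms —
the classical nested-design (animals within status, replicates within
animals) analysis. Coefficients are unchanged; only SE and df move. The
low-level fitters retain row-level inference when no grouping is given,
which reproduces the textbook pooled two-sample t on unit-level data.

Benjamini–Hochberg adjustment is applied across the tissue's full
metabolite complement (m = 51, 48, 37, 48 in the default design), via
`statsmodels.stats.multitest`. `adjust_fdr` also accepts a larger family
size m for adjusting a tested subset of a bigger family.

Metabolites with raw p < 0.05 get a second, sex-nested fit
`y = μ + sex + status(sex) + replicate_set`: a joint F-test of the
nested status terms plus per-sex t contrasts taken inside the full fit
(a config switch `per_sex_subset_fit` refits single-sex subsets
instead). A per-sex contrast is reported as NaN — never 0 or 1 — when
that sex contains a single status.

## Differential correlation

Technical replicates are averaged per animal first (the correlation
branch's replicate handling), and Pearson correlations are computed per
group for all m(m−1)/2 unordered pairs (canonical order: lexicographic).
Significance uses the exact small-sample t relation
`t = r·sqrt(n−2)/sqrt(1−r²)` on n−2 df.

Classification thresholds (configurable, defaults in parentheses):
strong means |r| > 0.9 with p < 0.05, sign-specific; weak means
|r| < 0.1 with p > 0.05; anything else is intermediate. The strong-side
p-threshold is 0.05: at n = 6, |r| = 0.9 gives p ≈ 0.0145, so a 10⁻⁴
threshold would be unattainable at this sample size. A pair strong in
one group and weak in the other is a candidate altered correlation.

The jackknife gate recomputes r on every leave-one-sample-out subset:
all strong-side subsets must keep a sign-matching |r| > 0.7 with
p < 0.05 (at subset size n−1 the p-condition is the binding one: for
n−1 = 5 it demands |r| > 0.878), and all weak-side subsets must keep
|r| < 0.2. Deleting one sample per group jointly is equivalent to
independent per-group leave-one-out, because each group's correlation
depends only on its own samples; the test suite verifies this against an
exhaustive joint-deletion oracle. The pass rule is *all* subsets, not a
majority — a single influential animal must not carry a classification.

Surviving candidates are tested with the two-sample Fisher r-to-z
statistic, `(atanh r₁ − atanh r₂)/sqrt(1/(n₁−3) + 1/(n₂−3))`, two-sided
against the standard normal; |r| = 1 is clamped to 1 − 10⁻¹² before the
transform and flagged. No multiplicity correction is applied across
pairs by default (matching the reference procedure); a config flag can
enable BH across candidate p-values. A pair is *altered* iff it is a
candidate, passes the jackknife, and has Fisher p < `fisher_alpha`.
Metabolites appearing in ≥ 2 altered pairs are reported as nodes with
their degree.

This gate is intentionally conservative at n = 6: on null cohorts the
altered rate is ~1–2% of candidates, and detection of a genuinely
group-specific pair is limited mostly by the requirement that the other
group classify weak — for an independent pair, P(|r| < 0.1) is ≈ 0.15
at n = 6 and ≈ 0.47 at n = 40 (the sampling SD of r under independence
is ≈ 1/√(n−1)). Full-gate detection therefore does **not** approach 1
as n grows; the weak gate, not the strong-side power, is asymptotically
binding. `scripts/acceptance.py` reports the measured rates.

## Synthetic cohorts

`SyntheticConfig` defaults encode the emulated study: 6 wild-type
(2 ewes, 4 rams) and 6 transgenic (3 ewes, 3 rams) animals; tissues
cerebellum/motor cortex/hippocampus/liver with 51/48/37/48 metabolites;
duplicate derivatizations. Per animal and tissue, the true log10
abundance of metabolite k is

    baseline_k + shift_k(status, sex) + biological_sd · b

with baselines uniform on [−1.2, 2.1] (the span of observed log10
means), biological_sd = 0.07 — chosen so that the between-animal SED at
n = 6 is ≈ 0.04, the magnitude reported for significant metabolites in
the reference design — and b standard normal. A planted pair shares a
latent factor f with loading λ inside its designated group
(`b = λf + sqrt(1−λ²)e`), giving population correlation λ² there and
independence elsewhere; one metabolite can carry at most one factor.
Each technical replicate adds independent Gaussian noise
(technical_sd = 0.02), and raw peak heights are
`10^(true + tech) × IS × pellet` with IS and pellet log-normal across
extractions (CV 0.10 and 0.15), so the normalization stage inverts the
construction exactly. The default study configuration plants 11
cerebellum and 15 liver mean shifts of 0.08–0.31 log10 units (one
negative, in the liver) and, per affected tissue, five transgenic-only
pairs at λ = 0.995 plus two both-group pairs at λ = 0.99.

Replicate averaging attenuates a planted pair's observable correlation
by σ_b²/(σ_b² + σ_t²/2) ≈ 0.96 at the default noise levels; tests that
need r ≈ 1 reduce technical_sd accordingly.

What the generator does *not* emulate: missingness mechanisms,
chromatographic drift or batch trends beyond the replicate-set offset,
metabolite-class-specific variance structure, and heavy-tailed or
skewed biological variation. Passing tests demonstrate correctness and
calibration of the statistics under Gaussian log-scale noise, not
robustness of the thresholds on real chromatograms.

## Numerical and reporting choices

* All model fits use explicit normal equations (rank-checked); this
  lets the simulation suites batch all metabolites of a tissue through
  one solve. The test suite pins them to statsmodels OLS and closed
  forms at 1e-8–1e-10.
* An exactly-zero contrast reports p = 1 even when the residual
  variance is 0; an undefined SD (single-animal group) is NaN, never 0.
* Correlations of constant vectors raise; |r| = 1 yields p reported as
  the 0 limit and a clamp flag on the Fisher transform.
* Status and sex tokens are case-insensitive on input and canonical on
  output; reporting rounds to 1 d.p. for cohort summaries while all
  computation keeps full precision.
* Simulation problem sizes in the test and acceptance suites (300–500
  seeds for null calibration, 500 seeds at n = 6 and 200 at n = 40 for
  detection, single-tissue cohorts for the per-seed loops) were chosen
  to bound Monte-Carlo error at roughly ±0.01–0.02 on the rates being
  checked; per-seed cohorts use one cerebellum-sized tissue since the
  checked rates are per-test and additional tissues only multiply
  runtime.

## Known limitations

* The per-sex contrasts at 2–4 animals per cell are fragile; they are
  reported as estimated, with no shrinkage or pooling.
* The between-animal inference assumes the two replicate sets share a
  single additive offset; replicate-set-by-metabolite interactions are
  not modelled.
* The differential-correlation gate's operating characteristics depend
  strongly on n through the weak-classification probability (see
  above); comparisons across cohorts of different size should compare
  against matched null simulations rather than raw counts.
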