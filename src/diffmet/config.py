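"""Run configuration: classification thresholds and alpha levels.

Defaults follow the study design this pipeline implements: a "strong"
pair correlation is |r| > 0.9 with p < 0.05, a "weak" one |r| < 0.1 with
p > 0.05, and the leave-one-out jackknife relaxes those to 0.7 / 0.2 to
compensate for the power lost with one sample removed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    strong_r_threshold: float = 0.9
    strong_p_threshold: float = 0.05
    weak_r_threshold: float = 0.1
    weak_p_threshold: float = 0.05
    jackknife_strong_threshold: float = 0.7
    jackknife_weak_threshold: float = 0.2
    fisher_alpha: float = 0.05
    fdr_alpha: float = 0.05
    # BH across pairs for the Fisher p-values; the reference procedure applies none
    fisher_fdr_across_pairs: bool = False
    # refit per-sex subsets instead of testing contrasts inside the nested fit
    per_sex_subset_fit: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.weak_r_threshold < self.jackknife_strong_threshold <= self.strong_r_threshold < 1):
            raise ValueError(
                "require 0 < weak_r_threshold < jackknife_strong_threshold "
                "<= strong_r_threshold < 1"
            )
        if not self.jackknife_weak_threshold > self.weak_r_threshold:
            raise ValueError("jackknife_weak_threshold must exceed weak_r_threshold")
        for name in ("strong_p_threshold", "weak_p_threshold", "fisher_alpha", "fdr_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
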