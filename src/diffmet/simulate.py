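"""Synthetic two-group GC-MS cohorts with known ground truth.

The generator emulates the study design this pipeline was built for: 6
wild-type (2 ewes, 4 rams) and 6 transgenic (3 ewes, 3 rams) animals,
four tissues with 51/48/37/48 metabolites, duplicate derivatizations per
extraction, and effects planted on the log10 scale:

* *mean shifts*: a per-metabolite group-mean offset of 0.08–0.31 log10
  units (the magnitude range of the differential abundances the design
  is calibrated to), optionally restricted to one sex;
* *planted correlations*: a metabolite pair shares a standard-normal
  latent factor with loading ``lambda`` inside the designated group, so
  the pair's population correlation there is lambda^2 while the other
  group stays independent.

True log10 abundances are baseline + shift + correlated component +
biological noise (SD 0.07, giving a standard error of the difference of
about 0.04 at n = 6 with duplicates); each technical replicate adds
independent noise (SD 0.02). Values are exponentiated and multiplied by
a simulated internal-standard abundance and pellet weight (log-normal
across extractions), so the normalization stage must exactly invert the
construction. Same seed, same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .types import AbundanceTable, CompoundClass, MetaboliteAnnotation, SampleRecord, Sex, Status

DEFAULT_TISSUES = ("cerebellum", "motor_cortex", "hippocampus", "liver")
DEFAULT_N_METABOLITES = {"cerebellum": 51, "motor_cortex": 48, "hippocampus": 37, "liver": 48}
#: amino-acid / fatty-acid / organic-acid counts per tissue (composition of
#: the profiles the generator emulates)
DEFAULT_CLASS_COUNTS = {
    "cerebellum": (21, 23, 7),
    "hippocampus": (19, 12, 6),
    "motor_cortex": (25, 18, 5),
    "liver": (23, 16, 9),
}


@dataclass(frozen=True)
class MeanShift:
    """A planted transgenic-minus-wild-type group mean shift (log10 units)."""

    tissue: str
    metabolite_index: int
    delta_log10: float
    sex_restriction: str = "both"  # both | ewe_only | ram_only


@dataclass(frozen=True)
class PlantedPair:
    """A planted latent-factor correlation between two metabolites."""

    tissue: str
    pair: tuple[int, int]
    group: str  # wt | tg | both
    latent_loading: float


@dataclass
class SyntheticConfig:
    n_wt: int = 6
    n_tg: int = 6
    sex_plan_wt: tuple[str, ...] = ("ewe", "ewe", "ram", "ram", "ram", "ram")
    sex_plan_tg: tuple[str, ...] = ("ewe", "ewe", "ewe", "ram", "ram", "ram")
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_metabolites: dict = field(default_factory=lambda: dict(DEFAULT_N_METABOLITES))
    mean_shift_plan: tuple[MeanShift, ...] = ()
    correlation_plan: tuple[PlantedPair, ...] = ()
    biological_sd: float = 0.07
    technical_sd: float = 0.02
    is_cv: float = 0.10
    pellet_cv: float = 0.15
    baseline_range: tuple[float, float] = (-1.2, 2.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wt < 2 or self.n_tg < 2:
            raise ValueError("each status group needs >= 2 animals")
        if len(self.sex_plan_wt) != self.n_wt or len(self.sex_plan_tg) != self.n_tg:
            raise ValueError("sex plan length must match group size")
        if self.biological_sd <= 0 or self.technical_sd <= 0:
            raise ValueError("noise SDs must be > 0")
        for pp in self.correlation_plan:
            if not 0 < pp.latent_loading < 1:
                raise ValueError("latent loading must lie in (0, 1)")
            if pp.tissue not in self.tissues:
                raise ValueError(f"planted pair references unknown tissue {pp.tissue!r}")
            if pp.group not in {"wt", "tg", "both"}:
                raise ValueError(f"planted-pair group must be wt/tg/both, got {pp.group!r}")
            if pp.pair[0] == pp.pair[1]:
                raise ValueError("planted pair must involve two distinct metabolites")
        for ms in self.mean_shift_plan:
            if ms.tissue not in self.tissues:
                raise ValueError(f"mean shift references unknown tissue {ms.tissue!r}")
            if ms.sex_restriction not in {"both", "ewe_only", "ram_only"}:
                raise ValueError(f"bad sex_restriction {ms.sex_restriction!r}")
        # one metabolite may carry at most one latent factor
        for tissue in self.tissues:
            seen: set[int] = set()
            for pp in self.correlation_plan:
                if pp.tissue != tissue:
                    continue
                for idx in pp.pair:
                    if idx in seen:
                        raise ValueError(
                            f"metabolite index {idx} in {tissue} appears in two planted pairs"
                        )
                    seen.add(idx)


#: mean shifts calibrated to the magnitudes observed in the study design
#: (cerebellum: 11 metabolites, all up; liver: 15, one down), applied to
#: the first metabolite indices of each affected tissue
_CEREBELLUM_DELTAS = (0.22, 0.19, 0.18, 0.23, 0.22, 0.25, 0.31, 0.14, 0.13, 0.18, 0.26)
_LIVER_DELTAS = (0.22, 0.28, 0.08, 0.21, 0.14, 0.10, -0.13, 0.10, 0.13, 0.17, 0.15, 0.16, 0.18, 0.17, 0.17)


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """The default study-condition cohort: planted shifts and planted pairs.

    Mean shifts follow the affected-tissue pattern (11 in cerebellum, 15
    in liver, magnitudes 0.08–0.31 log10 units). Five transgenic-only
    latent pairs at loading 0.995 and two both-group pairs at 0.99 are
    planted per affected tissue, on metabolites without mean shifts.
    """
    shifts = tuple(
        MeanShift("cerebellum", i, d) for i, d in enumerate(_CEREBELLUM_DELTAS)
    ) + tuple(MeanShift("liver", i, d) for i, d in enumerate(_LIVER_DELTAS))
    pairs = []
    for tissue, base in (("cerebellum", 20), ("liver", 20)):
        for k in range(5):
            pairs.append(PlantedPair(tissue, (base + 2 * k, base + 2 * k + 1), "tg", 0.995))
        for k in range(2):
            pairs.append(PlantedPair(tissue, (base + 10 + 2 * k, base + 11 + 2 * k), "both", 0.99))
    return SyntheticConfig(mean_shift_plan=shifts, correlation_plan=tuple(pairs), seed=seed)


def null_config(seed: int = 0, tissues: tuple[str, ...] = ("cerebellum",)) -> SyntheticConfig:
    """A cohort with no planted effects (for type-I-error studies)."""
    return SyntheticConfig(
        tissues=tissues,
        n_metabolites={t: DEFAULT_N_METABOLITES.get(t, 48) for t in tissues},
        seed=seed,
    )


def metabolite_names(tissue: str, m: int) -> list[str]:
    return [f"{tissue}_met{i:03d}" for i in range(m)]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    sigma = np.sqrt(np.log1p(cv * cv))
    mu = np.log(mean) - 0.5 * sigma * sigma
    return rng.lognormal(mu, sigma, size)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[SampleRecord], AbundanceTable, pd.DataFrame]:
    """Draw one cohort; returns (metadata, raw abundance table, truth ledger).

    The truth ledger has one row per planted effect with columns
    ``kind`` (mean_shift | corr_pair), ``tissue``, ``target`` (metabolite
    name or "a__b" pair id), ``group``, ``sex_restriction``, ``value``.
    """
    rng = np.random.default_rng(config.seed)
    animals = [("wt", i, s) for i, s in enumerate(config.sex_plan_wt)] + [
        ("tg", i, s) for i, s in enumerate(config.sex_plan_tg)
    ]
    metadata = []
    for group, i, sex_tok in animals:
        sex = Sex(sex_tok)
        heavier = sex is Sex.RAM
        metadata.append(
            SampleRecord(
                animal_id=f"{group}{i + 1}",
                status=Status.WILD_TYPE if group == "wt" else Status.TRANSGENIC,
                sex=sex,
                age_months=70 if heavier else 64,
                body_weight_kg=float(np.clip(rng.normal(91.7 if heavier else 76.8, 10.5 if heavier else 5.8), 40, 160)),
                brain_weight_g=float(np.clip(rng.normal(129.0, 7.0), 90, 180)),
                sampling_delay_min=float(np.clip(rng.normal(58.4 if heavier else 46.2, 4.9 if heavier else 4.0), 20, 120)),
            )
        )
    ids = [r.animal_id for r in metadata]
    group_of = {r.animal_id: ("tg" if r.status is Status.TRANSGENIC else "wt") for r in metadata}
    sex_of = {r.animal_id: r.sex.value for r in metadata}
    n_animals = len(ids)

    rec_frames = []
    ext_rows = []
    truth_rows = []
    ids_arr = np.array(ids)
    lo, hi = config.baseline_range
    for tissue in config.tissues:
        m = config.n_metabolites[tissue]
        names = metabolite_names(tissue, m)
        baseline = rng.uniform(lo, hi, m)

        shift = np.zeros((n_animals, m))
        for ms in config.mean_shift_plan:
            if ms.tissue != tissue:
                continue
            if not 0 <= ms.metabolite_index < m:
                raise ValueError(f"mean-shift index {ms.metabolite_index} out of range for {tissue}")
            for a, aid in enumerate(ids):
                if group_of[aid] != "tg":
                    continue
                if ms.sex_restriction == "ewe_only" and sex_of[aid] != "ewe":
                    continue
                if ms.sex_restriction == "ram_only" and sex_of[aid] != "ram":
                    continue
                shift[a, ms.metabolite_index] += ms.delta_log10
            truth_rows.append(
                {
                    "kind": "mean_shift",
                    "tissue": tissue,
                    "target": names[ms.metabolite_index],
                    "group": "tg",
                    "sex_restriction": ms.sex_restriction,
                    "value": ms.delta_log10,
                }
            )

        # biological component: independent noise, partially replaced by a
        # shared latent factor for planted pairs so that corr = lambda^2
        eps = rng.standard_normal((n_animals, m))
        bio = eps.copy()
        for pp in (p for p in config.correlation_plan if p.tissue == tissue):
            i, j = pp.pair
            if not (0 <= i < m and 0 <= j < m):
                raise ValueError(f"planted pair {pp.pair} out of range for {tissue}")
            lam = pp.latent_loading
            f = rng.standard_normal(n_animals)
            for a, aid in enumerate(ids):
                if pp.group in ("both", group_of[aid]):
                    bio[a, i] = lam * f[a] + np.sqrt(1 - lam * lam) * eps[a, i]
                    bio[a, j] = lam * f[a] + np.sqrt(1 - lam * lam) * eps[a, j]
            a_name, b_name = sorted((names[i], names[j]))
            truth_rows.append(
                {
                    "kind": "corr_pair",
                    "tissue": tissue,
                    "target": f"{a_name}__{b_name}",
                    "group": pp.group,
                    "sex_restriction": "both",
                    "value": pp.latent_loading,
                }
            )

        true_log10 = baseline[None, :] + shift + config.biological_sd * bio

        is_abund = _lognormal(rng, 1000.0, config.is_cv, n_animals)
        pellet = _lognormal(rng, 50.0, config.pellet_cv, n_animals)
        for a, aid in enumerate(ids):
            ext_rows.append(
                {
                    "animal_id": aid,
                    "tissue": tissue,
                    "internal_standard": is_abund[a],
                    "pellet_weight": pellet[a],
                }
            )
        for replicate in (1, 2):
            tech = rng.normal(0.0, config.technical_sd, (n_animals, m))
            raw = 10.0 ** (true_log10 + tech) * (is_abund * pellet)[:, None]
            rec_frames.append(
                pd.DataFrame(
                    {
                        "animal_id": np.repeat(ids_arr, m),
                        "tissue": tissue,
                        "replicate": replicate,
                        "metabolite": np.tile(np.array(names), n_animals),
                        "raw_abundance": raw.ravel(),
                    }
                )
            )

    table = AbundanceTable(
        records=pd.concat(rec_frames, ignore_index=True),
        extraction_info=pd.DataFrame(ext_rows),
    )
    truth = pd.DataFrame(
        truth_rows, columns=["kind", "tissue", "target", "group", "sex_restriction", "value"]
    )
    return metadata, table, truth


def generate_annotations(config: SyntheticConfig) -> list[MetaboliteAnnotation]:
    """Compound-class annotations matching the emulated per-tissue composition."""
    out = []
    classes = (
        CompoundClass.AMINO_ACID_OR_DERIVATIVE,
        CompoundClass.FATTY_ACID,
        CompoundClass.ORGANIC_ACID,
    )
    for tissue in config.tissues:
        m = config.n_metabolites[tissue]
        counts = DEFAULT_CLASS_COUNTS.get(tissue)
        if counts is None or sum(counts) != m:
            n_aa = round(0.45 * m)
            n_fa = round(0.40 * m)
            counts = (n_aa, n_fa, m - n_aa - n_fa)
        names = metabolite_names(tissue, m)
        k = 0
        for cls, n in zip(classes, counts):
            for _ in range(n):
                out.append(MetaboliteAnnotation(names[k], cls))
                k += 1
    return out


def write_truth_ledger(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_truth_ledger(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={c: str for c in ("kind", "tissue", "target", "group", "sex_restriction")},
        keep_default_na=False,
    )
    df["value"] = df["value"].astype(float)
    return df


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=seed)
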