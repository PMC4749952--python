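"""Core domain types for the pipeline.

The analysis unit is a small two-group animal cohort profiled by GC-MS:
raw peak heights per (animal, tissue, technical replicate, metabolite),
one internal-standard measurement and one dried-pellet weight per
extraction (animal x tissue), and per-animal metadata.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd


class Status(str, enum.Enum):
    """Transgene status of an animal."""

    WILD_TYPE = "wild_type"
    TRANSGENIC = "transgenic"


class Sex(str, enum.Enum):
    EWE = "ewe"
    RAM = "ram"


class CompoundClass(str, enum.Enum):
    AMINO_ACID_OR_DERIVATIVE = "amino_acid_or_derivative"
    FATTY_ACID = "fatty_acid"
    ORGANIC_ACID = "organic_acid"


class CorrelationClass(str, enum.Enum):
    """Strength classification of one group's pair correlation."""

    STRONG_POS = "strong_pos"
    STRONG_NEG = "strong_neg"
    WEAK = "weak"
    INTERMEDIATE = "intermediate"


#: canonical -> accepted input spellings (case-insensitive)
_STATUS_ALIASES = {
    Status.WILD_TYPE: {"wild_type", "wild-type", "wildtype", "wt"},
    Status.TRANSGENIC: {"transgenic", "tg", "ovt73"},
}
_SEX_ALIASES = {
    Sex.EWE: {"ewe", "female", "f"},
    Sex.RAM: {"ram", "male", "m"},
}


def parse_status(token: str) -> Status:
    t = str(token).strip().lower()
    for status, aliases in _STATUS_ALIASES.items():
        if t in aliases:
            return status
    raise ValueError(f"unknown transgene-status token: {token!r}")


def parse_sex(token: str) -> Sex:
    t = str(token).strip().lower()
    for sex, aliases in _SEX_ALIASES.items():
        if t in aliases:
            return sex
    raise ValueError(f"unknown sex token: {token!r}")


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one animal."""

    animal_id: str
    status: Status
    sex: Sex
    age_months: int
    body_weight_kg: float
    brain_weight_g: float
    sampling_delay_min: float

    def __post_init__(self) -> None:
        if not isinstance(self.status, Status):
            object.__setattr__(self, "status", parse_status(self.status))
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", parse_sex(self.sex))
        if self.age_months < 0:
            raise ValueError(f"{self.animal_id}: age_months must be >= 0")
        for name in ("body_weight_kg", "brain_weight_g", "sampling_delay_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{self.animal_id}: {name} must be > 0")


@dataclass
class AbundanceTable:
    """Raw peak heights plus per-extraction normalizer measurements.

    ``records`` columns: animal_id, tissue, replicate (1 or 2), metabolite,
    raw_abundance (>= 0, arbitrary units).
    ``extraction_info`` columns: animal_id, tissue, internal_standard (> 0),
    pellet_weight (> 0, arbitrary but consistent mass unit).
    """

    records: pd.DataFrame
    extraction_info: pd.DataFrame

    RECORD_COLUMNS = ("animal_id", "tissue", "replicate", "metabolite", "raw_abundance")
    EXTRACTION_COLUMNS = ("animal_id", "tissue", "internal_standard", "pellet_weight")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in self.RECORD_COLUMNS:
            if col not in self.records.columns:
                raise ValueError(f"abundance records missing column {col!r}")
        for col in self.EXTRACTION_COLUMNS:
            if col not in self.extraction_info.columns:
                raise ValueError(f"extraction info missing column {col!r}")
        rec = self.records
        bad_rep = ~rec["replicate"].isin([1, 2])
        if bad_rep.any():
            idx = rec.index[bad_rep][0]
            raise ValueError(f"replicate must be 1 or 2 (row {idx}: {rec.loc[idx, 'replicate']!r})")
        neg = rec["raw_abundance"].notna() & (rec["raw_abundance"] < 0)
        if neg.any():
            idx = rec.index[neg][0]
            raise ValueError(f"negative raw_abundance at row {idx}")
        key = ["animal_id", "tissue", "replicate", "metabolite"]
        if rec.duplicated(key).any():
            dup = rec[rec.duplicated(key, keep=False)].iloc[0]
            raise ValueError(
                "duplicate abundance record for "
                f"({dup.animal_id}, {dup.tissue}, {dup.replicate}, {dup.metabolite})"
            )
        ext = self.extraction_info
        if (ext["internal_standard"] <= 0).any() or (ext["pellet_weight"] <= 0).any():
            raise ValueError("internal_standard and pellet_weight must be > 0")
        if ext.duplicated(["animal_id", "tissue"]).any():
            raise ValueError("duplicate (animal_id, tissue) in extraction info")
        have = set(map(tuple, ext[["animal_id", "tissue"]].itertuples(index=False)))
        need = set(map(tuple, rec[["animal_id", "tissue"]].drop_duplicates().itertuples(index=False)))
        missing = need - have
        if missing:
            raise ValueError(f"no extraction info for (animal, tissue) pairs: {sorted(missing)[:5]}")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.records["tissue"].unique())


@dataclass(frozen=True)
class MetaboliteAnnotation:
    metabolite: str
    compound_class: CompoundClass

    def __post_init__(self) -> None:
        if not isinstance(self.compound_class, CompoundClass):
            object.__setattr__(self, "compound_class", CompoundClass(self.compound_class))


@dataclass
class NormalizedTable:
    """log10 relative abundances, one row per (animal, tissue, replicate, metabolite)."""

    records: pd.DataFrame  # columns: animal_id, tissue, replicate, metabolite, log10_rel_abundance

    @property
    def tissues(self) -> list[str]:
        return sorted(self.records["tissue"].unique())


@dataclass
class AveragedTable:
    """Replicate-averaged log10 relative abundances (correlation-branch input)."""

    records: pd.DataFrame  # columns: animal_id, tissue, metabolite, log10_rel_abundance

    def matrix(self, tissue: str) -> pd.DataFrame:
        """Animals x metabolites wide matrix for one tissue."""
        sub = self.records[self.records["tissue"] == tissue]
        return sub.pivot(index="animal_id", columns="metabolite", values="log10_rel_abundance")


@dataclass
class DiffAbundanceResult:
    """One metabolite's transgene contrast in one tissue."""

    metabolite: str
    mean_tg: float
    mean_wt: float
    sed: float
    p_raw: float
    p_fdr: float
    percent_diff: float
    compound_class: str | None = None


@dataclass
class NestedSexResult:
    """Sex-nested transgene contrasts; inestimable contrasts are NaN."""

    metabolite: str
    p_overall_nested: float
    p_ewe: float
    p_ram: float
    effect_ewe: float = float("nan")
    effect_ram: float = float("nan")


@dataclass
class CorrelationRecord:
    """One unordered metabolite pair's per-group Pearson correlations."""

    metabolite_a: str
    metabolite_b: str
    r_wt: float
    r_tg: float
    p_wt: float
    p_tg: float
    n_wt: int
    n_tg: int
    class_wt: CorrelationClass
    class_tg: CorrelationClass
    clamped: bool = False  # |r| = 1 hit the Fisher-transform clamp

    def __post_init__(self) -> None:
        if not self.metabolite_a < self.metabolite_b:
            raise ValueError("pair must be stored with metabolite_a < metabolite_b")


@dataclass
class DiffCorrelationResult:
    pair: tuple[str, str]
    candidate: bool
    jackknife_pass: bool
    z_wt: float
    z_tg: float
    z_stat: float
    p_fisher: float
    altered: bool
    strong_group: str | None = None  # "wt" or "tg" when candidate
    jackknife_r: dict = field(default_factory=dict)
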