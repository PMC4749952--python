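"""Readers, writers, completeness filtering and cohort summaries.

All files are plain UTF-8 CSV with a header row and "." decimal point.
Empty cells mean "not quantified"; no imputation is performed anywhere —
incompletely quantified metabolites are removed per tissue by
:func:`filter_complete_metabolites`, mirroring an analysis restricted to
metabolites quantified in every sample.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AbundanceTable,
    CompoundClass,
    MetaboliteAnnotation,
    SampleRecord,
    Sex,
    Status,
    parse_sex,
    parse_status,
)

METADATA_COLUMNS = (
    "animal_id",
    "status",
    "sex",
    "age_months",
    "body_weight_kg",
    "brain_weight_g",
    "sampling_delay_min",
)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{what} is missing required column {col!r}")


def read_abundance_table(path: str | Path, extraction_path: str | Path) -> AbundanceTable:
    """Read raw peak heights plus the companion extraction table."""
    rec = pd.read_csv(path)
    _require_columns(rec, AbundanceTable.RECORD_COLUMNS, f"abundance file {path}")
    ext = pd.read_csv(extraction_path)
    _require_columns(ext, AbundanceTable.EXTRACTION_COLUMNS, f"extraction file {extraction_path}")
    rec["animal_id"] = rec["animal_id"].astype(str)
    ext["animal_id"] = ext["animal_id"].astype(str)
    return AbundanceTable(records=rec, extraction_info=ext)


def write_abundance_table(table: AbundanceTable, path: str | Path, extraction_path: str | Path) -> None:
    table.records.to_csv(path, index=False)
    table.extraction_info.to_csv(extraction_path, index=False)


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"metadata file {path} contains no animals")
    _require_columns(df, METADATA_COLUMNS, f"metadata file {path}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                animal_id=str(row.animal_id),
                status=parse_status(row.status),
                sex=parse_sex(row.sex),
                age_months=int(row.age_months),
                body_weight_kg=float(row.body_weight_kg),
                brain_weight_g=float(row.brain_weight_g),
                sampling_delay_min=float(row.sampling_delay_min),
            )
        )
    return records


def write_sample_metadata(records: list[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "status": r.status.value,
                "sex": r.sex.value,
                "age_months": r.age_months,
                "body_weight_kg": r.body_weight_kg,
                "brain_weight_g": r.brain_weight_g,
                "sampling_delay_min": r.sampling_delay_min,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def load_packaged_cohort_metadata() -> list[SampleRecord]:
    """The packaged 12-animal sheep cohort (6 wild-type, 6 transgenic)."""
    with importlib.resources.as_file(
        importlib.resources.files("diffmet").joinpath("data/cohort_metadata.csv")
    ) as p:
        return read_sample_metadata(p)


def read_annotations(path: str | Path) -> list[MetaboliteAnnotation]:
    df = pd.read_csv(path)
    _require_columns(df, ("metabolite", "compound_class"), f"annotation file {path}")
    if df["metabolite"].duplicated().any():
        dup = df.loc[df["metabolite"].duplicated(), "metabolite"].iloc[0]
        raise ValueError(f"metabolite {dup!r} annotated more than once")
    return [
        MetaboliteAnnotation(str(m), CompoundClass(c))
        for m, c in zip(df["metabolite"], df["compound_class"])
    ]


def write_annotations(annotations: list[MetaboliteAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [{"metabolite": a.metabolite, "compound_class": a.compound_class.value} for a in annotations]
    ).to_csv(path, index=False)


def filter_complete_metabolites(table: AbundanceTable) -> tuple[AbundanceTable, dict[str, int]]:
    """Drop metabolites not quantified in every (animal, replicate) of a tissue.

    A metabolite is retained in a tissue only if a non-missing abundance is
    recorded for every (animal, replicate) combination present in that
    tissue. Returns the filtered table and the per-tissue retained counts.
    """
    rec = table.records
    keep_parts = []
    retained: dict[str, int] = {}
    for tissue, sub in rec.groupby("tissue", sort=True):
        n_units = sub[["animal_id", "replicate"]].drop_duplicates().shape[0]
        quantified = sub[sub["raw_abundance"].notna()]
        counts = quantified.groupby("metabolite")[["animal_id"]].size()
        complete = set(counts[counts == n_units].index)
        retained[tissue] = len(complete)
        keep_parts.append(sub[sub["metabolite"].isin(complete)])
    kept = pd.concat(keep_parts, ignore_index=True) if keep_parts else rec.iloc[0:0]
    return AbundanceTable(records=kept, extraction_info=table.extraction_info), retained


def compose_class_summary(
    annotations: list[MetaboliteAnnotation], retained: list[str]
) -> pd.DataFrame:
    """Per-class composition of a retained metabolite set, as percentages.

    Returns a one-row-per-class frame with counts and percentages of the
    total (percentages sum to 100 before rounding).
    """
    lookup = {a.metabolite: a.compound_class for a in annotations}
    missing = [m for m in retained if m not in lookup]
    if missing:
        raise ValueError(f"metabolite {missing[0]!r} has no compound-class annotation")
    total = len(retained)
    rows = []
    for cls in CompoundClass:
        n = sum(1 for m in retained if lookup[m] is cls)
        rows.append(
            {
                "compound_class": cls.value,
                "count": n,
                "percent": 100.0 * n / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(records: list[SampleRecord]) -> pd.DataFrame:
    """Per-sex mean and sample SD (n-1) of body weight and sampling delay.

    SD is NaN for a single-animal sex group, never reported as 0.
    """
    if not records:
        raise ValueError("no animals to summarize")
    rows = []
    for sex in Sex:
        group = [r for r in records if r.sex is sex]
        if not group:
            continue
        weights = np.array([r.body_weight_kg for r in group], dtype=float)
        delays = np.array([r.sampling_delay_min for r in group], dtype=float)
        n = len(group)
        rows.append(
            {
                "sex": sex.value,
                "n": n,
                "body_weight_mean": weights.mean(),
                "body_weight_sd": weights.std(ddof=1) if n >= 2 else np.nan,
                "sampling_delay_mean": delays.mean(),
                "sampling_delay_sd": delays.std(ddof=1) if n >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def status_of(records: list[SampleRecord]) -> dict[str, Status]:
    return {r.animal_id: r.status for r in records}


def sex_of(records: list[SampleRecord]) -> dict[str, Sex]:
    return {r.animal_id: r.sex for r in records}
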