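"""Normalization of raw peak heights to log10 relative abundances.

Each raw peak height is divided by the extraction's internal-standard
abundance and by its dried-pellet weight, then log10-transformed. The
internal standard corrects extraction-efficiency variation; the pellet
weight corrects the amount of starting material. Both enter as a single
multiplicative factor per extraction, so downstream per-tissue group
contrasts on the log scale are invariant to their units.

Replicate handling differs by branch: the differential-abundance models
keep the two technical replicates as separate rows (with a replicate-set
fixed effect), while the correlation branch averages them per animal
first (:func:`average_technical_replicates`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import AbundanceTable, AveragedTable, NormalizedTable


def normalize_abundance(raw: float, internal_standard: float, pellet_weight: float) -> float:
    """Relative abundance: raw / (internal_standard * pellet_weight)."""
    if internal_standard <= 0:
        raise ValueError("internal_standard must be > 0")
    if pellet_weight <= 0:
        raise ValueError("pellet_weight must be > 0")
    if raw < 0:
        raise ValueError("raw abundance must be >= 0")
    return raw / (internal_standard * pellet_weight)


def log_transform(rel: float) -> float:
    """Base-10 logarithm of a positive relative abundance."""
    if rel <= 0:
        raise ValueError("relative abundance must be > 0 for log transform")
    return float(np.log10(rel))


def back_transform_percent(delta_log10: float) -> float:
    """Signed percent difference implied by a log10-scale mean difference.

    ``(10**delta - 1) * 100``: 0 at delta = 0, +100% at delta = log10(2).
    """
    return (10.0 ** delta_log10 - 1.0) * 100.0


def normalize_table(table: AbundanceTable) -> NormalizedTable:
    """Tablewise normalization and log10 transform.

    Rows with missing raw abundance stay missing. A raw abundance of 0
    has no defined log and is treated as "not quantified" (missing); the
    metabolite will then fail the completeness filter for that tissue.
    """
    rec = table.records.merge(
        table.extraction_info, on=["animal_id", "tissue"], how="left", validate="many_to_one"
    )
    rel = rec["raw_abundance"] / (rec["internal_standard"] * rec["pellet_weight"])
    with np.errstate(divide="ignore"):
        log10 = np.log10(rel.where(rel > 0))
    out = rec[["animal_id", "tissue", "replicate", "metabolite"]].copy()
    out["log10_rel_abundance"] = log10
    out = out[out["log10_rel_abundance"].notna()].reset_index(drop=True)
    return NormalizedTable(records=out)


def average_technical_replicates(table: NormalizedTable) -> AveragedTable:
    """Arithmetic mean of the available replicate values on the log10 scale."""
    rec = table.records
    if rec.empty:
        raise ValueError("cannot average an empty table")
    grouped = (
        rec.groupby(["animal_id", "tissue", "metabolite"], sort=True, as_index=False)[
            "log10_rel_abundance"
        ].mean()
    )
    return AveragedTable(records=grouped)


def normalized_matrix(table: NormalizedTable, tissue: str) -> pd.DataFrame:
    """(animal, replicate) x metabolite wide matrix for one tissue."""
    sub = table.records[table.records["tissue"] == tissue]
    return sub.pivot(index=["animal_id", "replicate"], columns="metabolite", values="log10_rel_abundance")
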