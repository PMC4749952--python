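"""Per-metabolite least-squares transgene contrasts with FDR control.

Model, per metabolite within one tissue::

    log10 relative abundance = intercept + status + replicate_set

fitted by ordinary least squares on the replicate-level rows. The
replicate-set term is an additive fixed effect for the two sequentially
derivatized/measured technical-replicate sets; it is dropped when only
one set is present. The transgene effect is the transgenic-minus-wild-type
least-squares-mean contrast, which in this additive coding is the status
coefficient, and in a balanced design equals the difference of raw group
means.

Inference respects the experimental unit. Technical replicates of one
extraction share the animal's biological deviation, so they are not
independent errors for a between-animal contrast; when the animal
grouping is supplied, the contrast's standard error and degrees of
freedom come from the between-animal stratum (replicate-set-adjusted
animal means), the classical nested-design analysis. Without a grouping,
rows are treated as independent units. Benjamini–Hochberg adjustment is
applied across all metabolites of the tissue.

Sex-specificity is probed by a second model nesting status within sex::

    response = intercept + sex + status-within-sex + replicate_set

with a joint F-test of the nested status terms and per-sex t contrasts.
All fits use explicit normal equations so that the multi-hundred-seed
simulation suites can batch metabolites through one matrix solve; the
test suite checks them against an independent OLS implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .preprocess import back_transform_percent
from .types import DiffAbundanceResult, NestedSexResult, NormalizedTable, SampleRecord, Sex, Status


@dataclass
class _Fit:
    beta: np.ndarray  # (k, m)
    se: np.ndarray  # (k, m)
    df_resid: int
    rss: np.ndarray  # (m,)


def _ols(X: np.ndarray, Y: np.ndarray) -> _Fit:
    """OLS of every column of Y on X; X must have full column rank."""
    n, k = X.shape
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < k:
        raise ValueError("design matrix is rank deficient")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - k
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    return _Fit(beta=beta, se=se, df_resid=df, rss=rss)


def _t_pvalue(effect: np.ndarray, se: np.ndarray, df: int) -> np.ndarray:
    """Two-sided t-test; an exactly-zero effect has p = 1 even if se = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(effect == 0.0, 0.0, effect / se)
    return 2.0 * stats.t.sf(np.abs(t), df)


def _batch_column(batch) -> np.ndarray | None:
    if batch is None:
        return None
    b = np.asarray(batch)
    if len(np.unique(b)) < 2:
        return None
    return (b == np.max(b)).astype(float)


def _animal_means(Y: np.ndarray, animal: np.ndarray, batch_col: np.ndarray | None, batch_beta: np.ndarray | None):
    """Replicate-set-adjusted per-animal means.

    Subtracts the estimated replicate-set effect from second-set rows and
    averages each animal's rows; with one row per animal per set this is
    an orthogonal reduction and the adjustment cancels in group contrasts.
    """
    animal = np.asarray(animal)
    uniq, inv = np.unique(animal, return_inverse=True)
    counts = np.bincount(inv).astype(float)
    if counts.min() < 1:
        raise ValueError("every animal needs at least one replicate row")
    Yadj = Y if batch_col is None else Y - np.outer(batch_col, batch_beta)
    A = np.zeros((uniq.size, animal.size))
    A[inv, np.arange(animal.size)] = 1.0 / counts[inv]
    return uniq, inv, A @ Yadj


def fit_transgene_model_batch(
    Y: np.ndarray,
    status_tg: np.ndarray,
    batch: np.ndarray | None = None,
    animal: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized transgene fit for an (observations x metabolites) matrix.

    ``status_tg`` is 1 for transgenic rows, 0 for wild-type; ``batch`` the
    replicate-set label per row (or None to omit the term); ``animal`` the
    grouping of rows into experimental units (or None to treat rows as
    independent).
    """
    status_tg = np.asarray(status_tg).astype(int)
    if status_tg.min() == status_tg.max():
        raise ValueError("both status groups must be present")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != status_tg.shape[0]:
        Y = Y.T
    batch_col = _batch_column(batch)

    cols = [np.ones(Y.shape[0]), status_tg.astype(float)]
    if batch_col is not None:
        cols.append(batch_col)
    row_fit = _ols(np.column_stack(cols), Y)
    mean_tg = Y[status_tg == 1].mean(axis=0)
    mean_wt = Y[status_tg == 0].mean(axis=0)

    if animal is None:
        if min((status_tg == 0).sum(), (status_tg == 1).sum()) < 2:
            raise ValueError("need at least 2 observations per status group")
        effect, sed = row_fit.beta[1], row_fit.se[1]
        df = row_fit.df_resid
    else:
        batch_beta = row_fit.beta[2] if batch_col is not None else None
        uniq, inv, Ym = _animal_means(Y, animal, batch_col, batch_beta)
        status_a = np.array([status_tg[inv == i][0] for i in range(uniq.size)])
        if np.any([len(np.unique(status_tg[inv == i])) > 1 for i in range(uniq.size)]):
            raise ValueError("an animal cannot belong to both status groups")
        if min((status_a == 0).sum(), (status_a == 1).sum()) < 2:
            raise ValueError("need at least 2 animals per status group")
        unit_fit = _ols(np.column_stack([np.ones(uniq.size), status_a.astype(float)]), Ym)
        effect, sed = unit_fit.beta[1], unit_fit.se[1]
        df = unit_fit.df_resid
    return {
        "effect": effect,
        "sed": sed,
        "p_raw": _t_pvalue(effect, sed, df),
        "mean_tg": mean_tg,
        "mean_wt": mean_wt,
        "df_resid": df,
    }


def fit_transgene_model(values, status, batch=None, animal=None) -> tuple[float, float, float, float, float]:
    """Single-metabolite transgene contrast.

    Parameters
    ----------
    values : array-like of log10 relative abundances (one per row)
    status : array-like of {wild_type, transgenic} labels (or 0/1)
    batch : optional replicate-set label per row
    animal : optional experimental-unit (animal) id per row; when given,
        the contrast is tested against between-animal variation

    Returns ``(effect, sed, p_raw, mean_tg, mean_wt)`` with effect the
    transgenic-minus-wild-type contrast.
    """
    out = fit_transgene_model_batch(
        np.asarray(values, dtype=float)[:, None], _status_indicator(status), batch, animal
    )
    return (
        float(out["effect"][0]),
        float(out["sed"][0]),
        float(out["p_raw"][0]),
        float(out["mean_tg"][0]),
        float(out["mean_wt"][0]),
    )


def _status_indicator(status) -> np.ndarray:
    arr = np.asarray(status)
    if arr.dtype.kind in "ifb":
        return arr.astype(int)
    out = np.empty(arr.shape[0], dtype=int)
    for i, s in enumerate(arr):
        s = s.value if isinstance(s, Status) else str(s).strip().lower()
        out[i] = 1 if s in {"transgenic", "tg", "ovt73"} else 0
    return out


def _sex_labels(sex) -> np.ndarray:
    arr = np.asarray(sex)
    out = np.empty(arr.shape[0], dtype="U3")
    for i, s in enumerate(arr):
        out[i] = s.value if isinstance(s, Sex) else str(s).strip().lower()
    return out


def fit_nested_sex_model(values, status, sex, batch=None, animal=None) -> NestedSexResult:
    """Status-within-sex nested model for one metabolite.

    Fits ``response = intercept + sex + status-within-sex (+ replicate_set)``.
    ``p_overall_nested`` is the joint F-test of the nested status terms;
    ``p_ewe`` / ``p_ram`` are the per-sex transgene t contrasts. A contrast
    that is inestimable because one sex contains a single status is NaN.
    As in :func:`fit_transgene_model`, supplying ``animal`` moves
    inference to the between-animal stratum.
    """
    y = np.asarray(values, dtype=float)[:, None]
    status_tg = _status_indicator(status)
    sex_lab = _sex_labels(sex)
    batch_col = _batch_column(batch)

    if animal is not None:
        row_cols = [np.ones(y.shape[0]), (sex_lab == "ram").astype(float)]
        for s in ("ewe", "ram"):
            col = ((sex_lab == s) & (status_tg == 1)).astype(float)
            if 0 < col.sum() < (sex_lab == s).sum():
                row_cols.append(col)
        batch_beta = None
        if batch_col is not None:
            row_cols.append(batch_col)
            batch_beta = _ols(np.column_stack(row_cols), y).beta[-1]
        uniq, inv, y = _animal_means(y, animal, batch_col, batch_beta)
        status_tg = np.array([status_tg[inv == i][0] for i in range(uniq.size)])
        sex_lab = np.array([sex_lab[inv == i][0] for i in range(uniq.size)])
        batch_col = None
    n = y.shape[0]

    estimable = {}
    for s in ("ewe", "ram"):
        in_sex = sex_lab == s
        estimable[s] = bool(in_sex.any() and len(np.unique(status_tg[in_sex])) == 2)
    if not any(estimable.values()):
        raise ValueError("no sex group contains both transgene statuses")

    cols = [np.ones(n), (sex_lab == "ram").astype(float)]
    names = ["intercept", "sex_ram"]
    nested_idx = {}
    for s in ("ewe", "ram"):
        if estimable[s]:
            nested_idx[s] = len(cols)
            cols.append(((sex_lab == s) & (status_tg == 1)).astype(float))
            names.append(f"tg_within_{s}")
    if batch_col is not None:
        cols.append(batch_col)
        names.append("batch2")
    X = np.column_stack(cols)
    full = _ols(X, y)

    # reduced model without the nested status columns, for the joint F-test
    keep = [i for i, nm in enumerate(names) if not nm.startswith("tg_within_")]
    reduced = _ols(X[:, keep], y)
    q = len(nested_idx)
    f_num = (reduced.rss[0] - full.rss[0]) / q
    f_den = full.rss[0] / full.df_resid
    if f_den == 0:
        p_overall = 1.0 if f_num == 0 else 0.0
    else:
        p_overall = float(stats.f.sf(f_num / f_den, q, full.df_resid))

    p_sex = {"ewe": math.nan, "ram": math.nan}
    eff_sex = {"ewe": math.nan, "ram": math.nan}
    for s, j in nested_idx.items():
        eff_sex[s] = float(full.beta[j, 0])
        p_sex[s] = float(_t_pvalue(full.beta[j], full.se[j], full.df_resid)[0])

    return NestedSexResult(
        metabolite="",
        p_overall_nested=p_overall,
        p_ewe=p_sex["ewe"],
        p_ram=p_sex["ram"],
        effect_ewe=eff_sex["ewe"],
        effect_ram=eff_sex["ram"],
    )


def _fit_per_sex_subsets(values, status, sex, batch, animal) -> dict[str, float]:
    """Alternative per-sex contrasts from refitting each single-sex subset."""
    y = np.asarray(values, dtype=float)
    status_tg = _status_indicator(status)
    sex_lab = _sex_labels(sex)
    out = {}
    for s in ("ewe", "ram"):
        mask = sex_lab == s
        if mask.any() and len(np.unique(status_tg[mask])) == 2 and min(
            (status_tg[mask] == 0).sum(), (status_tg[mask] == 1).sum()
        ) >= 2:
            b = np.asarray(batch)[mask] if batch is not None else None
            a = np.asarray(animal)[mask] if animal is not None else None
            try:
                _, _, p, _, _ = fit_transgene_model(y[mask], status_tg[mask], b, a)
            except ValueError:
                p = math.nan
            out[s] = p
        else:
            out[s] = math.nan
    return out


def adjust_fdr(p_values, m: int | None = None) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``m`` defaults to the list length; a larger ``m`` treats the input as
    the tested subset of a larger family (each p is scaled by m/rank
    before the step-up minimum).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None or m == p.size:
        return list(multipletests(p, method="fdr_bh")[1])
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return list(out)


def run_diffabund(
    table: NormalizedTable,
    metadata: list[SampleRecord],
    tissue: str,
    config: RunConfig | None = None,
    annotations: dict[str, str] | None = None,
) -> tuple[list[DiffAbundanceResult], list[NestedSexResult]]:
    """Differential abundance for one tissue.

    One result per metabolite, FDR-adjusted across all metabolites of the
    tissue; the nested sex model is fitted only for metabolites with
    nominally significant (p < 0.05) transgene effects, mirroring
    two-stage reporting. Results are sorted by raw p-value.
    """
    config = config or RunConfig()
    status_by_animal = {r.animal_id: r.status for r in metadata}
    sex_by_animal = {r.animal_id: r.sex for r in metadata}
    sub = table.records[table.records["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"no records for tissue {tissue!r}")
    wide = sub.pivot(index=["animal_id", "replicate"], columns="metabolite", values="log10_rel_abundance")
    if wide.isna().any().any():
        raise ValueError("tissue table is not completeness-filtered (missing cells present)")
    animals = wide.index.get_level_values("animal_id").to_numpy()
    unknown = set(animals) - set(status_by_animal)
    if unknown:
        raise ValueError(f"animals without metadata: {sorted(unknown)}")
    status_tg = np.array([1 if status_by_animal[a] is Status.TRANSGENIC else 0 for a in animals])
    sex = np.array([sex_by_animal[a].value for a in animals])
    batch = wide.index.get_level_values("replicate").to_numpy()

    Y = wide.to_numpy()
    fit = fit_transgene_model_batch(Y, status_tg, batch, animals)
    p_fdr = adjust_fdr(fit["p_raw"])

    results = []
    for j, met in enumerate(wide.columns):
        delta = float(fit["mean_tg"][j] - fit["mean_wt"][j])
        results.append(
            DiffAbundanceResult(
                metabolite=met,
                mean_tg=float(fit["mean_tg"][j]),
                mean_wt=float(fit["mean_wt"][j]),
                sed=float(fit["sed"][j]),
                p_raw=float(fit["p_raw"][j]),
                p_fdr=float(p_fdr[j]),
                percent_diff=back_transform_percent(delta),
                compound_class=(annotations or {}).get(met),
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.metabolite))

    nested = []
    for res in results:
        if res.p_raw < 0.05:
            y = wide[res.metabolite].to_numpy()
            nr = fit_nested_sex_model(y, status_tg, sex, batch, animals)
            if config.per_sex_subset_fit:
                sub_p = _fit_per_sex_subsets(y, status_tg, sex, batch, animals)
                nr.p_ewe, nr.p_ram = sub_p["ewe"], sub_p["ram"]
            nr.metabolite = res.metabolite
            nested.append(nr)
    return results, nested


def diffabund_frame(results: list[DiffAbundanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite,
                "mean_tg": r.mean_tg,
                "mean_wt": r.mean_wt,
                "sed": r.sed,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "percent_diff": r.percent_diff,
                "compound_class": r.compound_class,
            }
            for r in results
        ]
    )


def nested_frame(results: list[NestedSexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite,
                "p_overall_nested": r.p_overall_nested,
                "p_ewe": r.p_ewe,
                "p_ram": r.p_ram,
                "effect_ewe": r.effect_ewe,
                "effect_ram": r.effect_ram,
            }
            for r in results
        ]
    )
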