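"""Differential (group-altered) correlation screen.

For every unordered metabolite pair, Pearson correlations are computed
separately in the wild-type and transgenic groups on replicate-averaged
log10 relative abundances and classified:

* strong:  |r| > 0.9 and p < 0.05 (sign-specific, ``strong_pos``/``strong_neg``)
* weak:    |r| < 0.1 and p > 0.05
* intermediate: anything else

A pair that is strong in one group but weak in the other is a
*candidate* altered correlation. Candidates are screened for outlier
artifacts by a leave-one-sample-out jackknife: every deletion subset of
the strong-side group must keep a sign-matching |r| > 0.7 with p < 0.05,
and every subset of the weak-side group must keep |r| < 0.2 (thresholds
relaxed relative to the full-sample definitions to compensate for the
power lost with one sample removed). Surviving candidates are tested for
a significant between-group difference with the Fisher r-to-z two-sample
test; pairs significant at ``fisher_alpha`` are flagged *altered*.
Metabolites participating in two or more altered pairs are reported as
network *nodes*.

The per-pair scalar operations are exposed individually; ``run_diffcorr``
uses vectorized all-pairs matrices internally so that the multi-hundred
seed simulation suites stay fast.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .types import CorrelationClass, CorrelationRecord, DiffCorrelationResult

_CLAMP = 1.0 - 1e-12


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def correlation_p(r: float, n: int) -> float:
    """Two-sided p for a sample correlation, t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2."""
    if n < 4:
        raise ValueError("need n >= 4 for a correlation p-value")
    if abs(r) >= 1.0:
        return 0.0  # degenerate limit; callers flag clamping separately
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _p_matrix(r: np.ndarray, n: int) -> np.ndarray:
    rr = np.clip(r, -_CLAMP, _CLAMP)
    t = rr * np.sqrt(n - 2) / np.sqrt(1.0 - rr * rr)
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


def classify_correlation(r: float, p: float, config: RunConfig | None = None) -> CorrelationClass:
    """Strength class of one group's correlation (pure function of r, p, config)."""
    config = config or RunConfig()
    if r > config.strong_r_threshold and p < config.strong_p_threshold:
        return CorrelationClass.STRONG_POS
    if r < -config.strong_r_threshold and p < config.strong_p_threshold:
        return CorrelationClass.STRONG_NEG
    if abs(r) < config.weak_r_threshold and p > config.weak_p_threshold:
        return CorrelationClass.WEAK
    return CorrelationClass.INTERMEDIATE


# integer codes for vectorized classification
_STRONG_POS, _STRONG_NEG, _WEAK, _INTERMEDIATE = 1, 2, 3, 0
_CODE_TO_CLASS = {
    _STRONG_POS: CorrelationClass.STRONG_POS,
    _STRONG_NEG: CorrelationClass.STRONG_NEG,
    _WEAK: CorrelationClass.WEAK,
    _INTERMEDIATE: CorrelationClass.INTERMEDIATE,
}


def _classify_matrix(r: np.ndarray, p: np.ndarray, config: RunConfig) -> np.ndarray:
    cls = np.full(r.shape, _INTERMEDIATE, dtype=np.int8)
    cls[(r > config.strong_r_threshold) & (p < config.strong_p_threshold)] = _STRONG_POS
    cls[(r < -config.strong_r_threshold) & (p < config.strong_p_threshold)] = _STRONG_NEG
    cls[(np.abs(r) < config.weak_r_threshold) & (p > config.weak_p_threshold)] = _WEAK
    return cls


def enumerate_pairs(metabolites) -> list[tuple[str, str]]:
    """All m(m-1)/2 unordered pairs, canonically (lexicographically) ordered."""
    names = list(metabolites)
    if len(set(names)) != len(names):
        raise ValueError("metabolite names must be unique")
    return list(itertools.combinations(sorted(names), 2))


def fisher_r_to_z_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample Fisher r-to-z comparison of independent correlations.

    z_i = atanh(r_i); the statistic (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))
    is referred to the standard normal, two-sided. |r| = 1 is clamped to
    1 - 1e-12 to avoid the atanh divergence on degenerate data.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher r-to-z requires n > 3 in both groups")
    z1 = np.arctanh(np.clip(r1, -_CLAMP, _CLAMP))
    z2 = np.arctanh(np.clip(r2, -_CLAMP, _CLAMP))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = float((z1 - z2) / se)
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    return z_stat, p


def jackknife_validate(
    pair: tuple[str, str],
    wt_values: np.ndarray,
    tg_values: np.ndarray,
    config: RunConfig | None = None,
) -> tuple[bool, dict[str, list[float]]]:
    """Leave-one-out stability screen for a candidate pair.

    ``wt_values`` / ``tg_values``: (n, 2) arrays of the pair's
    replicate-averaged values in each group. Each group's correlation
    depends only on its own samples, so deleting one sample per group is
    evaluated as independent per-group leave-one-out. The strong-side
    group must keep a sign-matching |r| above
    ``jackknife_strong_threshold`` with p < 0.05 in every deletion
    subset; the weak-side group must keep |r| below
    ``jackknife_weak_threshold`` in every subset.

    Returns (pass, {"wt": [...], "tg": [...]}) with the per-deletion r
    values (entry i = sample i removed).
    """
    config = config or RunConfig()
    wt = np.asarray(wt_values, dtype=float)
    tg = np.asarray(tg_values, dtype=float)
    for name, arr in (("wild-type", wt), ("transgenic", tg)):
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"{name} values must be an (n, 2) array")
        if arr.shape[0] < 5:
            raise ValueError(f"{name} group needs >= 5 samples for the jackknife")

    def full_class(arr):
        r = pearson_r(arr[:, 0], arr[:, 1])
        return classify_correlation(r, correlation_p(r, arr.shape[0]), config), r

    cls_wt, r_wt = full_class(wt)
    cls_tg, r_tg = full_class(tg)
    strong = {CorrelationClass.STRONG_POS, CorrelationClass.STRONG_NEG}
    if cls_wt in strong and cls_tg is CorrelationClass.WEAK:
        strong_arr, weak_arr, sign = wt, tg, np.sign(r_wt)
    elif cls_tg in strong and cls_wt is CorrelationClass.WEAK:
        strong_arr, weak_arr, sign = tg, wt, np.sign(r_tg)
    else:
        raise ValueError(f"pair {pair} is not a strong/weak candidate")

    def loo_r(arr):
        n = arr.shape[0]
        out = []
        for i in range(n):
            sub = np.delete(arr, i, axis=0)
            out.append(pearson_r(sub[:, 0], sub[:, 1]))
        return out

    strong_rs = loo_r(strong_arr)
    weak_rs = loo_r(weak_arr)
    n_sub_strong = strong_arr.shape[0] - 1
    ok_strong = all(
        sign * r > config.jackknife_strong_threshold and correlation_p(r, n_sub_strong) < 0.05
        for r in strong_rs
    )
    ok_weak = all(abs(r) < config.jackknife_weak_threshold for r in weak_rs)
    passed = bool(ok_strong and ok_weak)
    per_group = {"wt": strong_rs, "tg": weak_rs} if strong_arr is wt else {"wt": weak_rs, "tg": strong_rs}
    return passed, per_group


def find_candidates(records: list[CorrelationRecord]) -> list[CorrelationRecord]:
    """Pairs strong in one group and weak in the other (either direction)."""
    strong = {CorrelationClass.STRONG_POS, CorrelationClass.STRONG_NEG}
    return [
        rec
        for rec in records
        if (rec.class_wt in strong and rec.class_tg is CorrelationClass.WEAK)
        or (rec.class_tg in strong and rec.class_wt is CorrelationClass.WEAK)
    ]


def detect_nodes(altered: list[DiffCorrelationResult]) -> dict[str, int]:
    """Metabolites in >= 2 altered pairs, mapped to their altered-pair degree."""
    degree: dict[str, int] = {}
    for res in altered:
        if not res.altered:
            continue
        for met in res.pair:
            degree[met] = degree.get(met, 0) + 1
    return {m: d for m, d in degree.items() if d >= 2}


def count_strong_pairs(
    wt: pd.DataFrame, tg: pd.DataFrame, config: RunConfig | None = None
) -> dict[str, int]:
    """Strong-pair census: per-group and shared strong counts plus pair total."""
    config = config or RunConfig()
    _check_matrices(wt, tg)
    m = wt.shape[1]
    iu = np.triu_indices(m, k=1)
    strong_masks = []
    for arr in (wt, tg):
        r = np.corrcoef(arr.to_numpy(), rowvar=False)
        p = _p_matrix(r, arr.shape[0])
        cls = _classify_matrix(r, p, config)[iu]
        strong_masks.append((cls == _STRONG_POS) | (cls == _STRONG_NEG))
    wt_strong, tg_strong = strong_masks
    return {
        "wt_strong": int(wt_strong.sum()),
        "tg_strong": int(tg_strong.sum()),
        "shared_strong": int((wt_strong & tg_strong).sum()),
        "total": m * (m - 1) // 2,
    }


def _check_matrices(wt: pd.DataFrame, tg: pd.DataFrame) -> None:
    if list(wt.columns) != list(tg.columns):
        if set(wt.columns) != set(tg.columns):
            raise ValueError("wild-type and transgenic tables cover different metabolite sets")
        raise ValueError("metabolite columns must be in the same order in both groups")
    for name, df in (("wild-type", wt), ("transgenic", tg)):
        if df.isna().any().any():
            raise ValueError(f"{name} table has missing values; filter completeness first")
        if (df.std(axis=0) == 0).any():
            const = df.columns[(df.std(axis=0) == 0)][0]
            raise ValueError(f"{name} metabolite {const!r} is constant; correlation undefined")


@dataclass
class DiffCorrOutput:
    """Everything ``run_diffcorr`` produces for one tissue."""

    results: list[DiffCorrelationResult]  # one per candidate pair
    records: list[CorrelationRecord]  # per-group correlations of candidate pairs
    counts: dict[str, int]
    nodes: dict[str, int]
    pair_frame: pd.DataFrame | None = None  # all pairs, vectorized summary
    scatter: pd.DataFrame | None = None  # per-sample values of altered pairs

    @property
    def altered(self) -> list[DiffCorrelationResult]:
        return [r for r in self.results if r.altered]


def run_diffcorr(
    wt: pd.DataFrame,
    tg: pd.DataFrame,
    config: RunConfig | None = None,
    collect_pairs: bool = True,
) -> DiffCorrOutput:
    """Full differential-correlation screen for one tissue.

    ``wt``/``tg`` are animals x metabolites matrices of replicate-averaged
    log10 relative abundances with identical columns. Pipeline order:
    classify -> candidates -> jackknife -> Fisher r-to-z -> altered flag;
    only pairs passing all three gates are flagged altered.

    ``collect_pairs=False`` skips the all-pairs summary frame and scatter
    export (used by the simulation suites).
    """
    config = config or RunConfig()
    _check_matrices(wt, tg)
    order = np.argsort(wt.columns.to_numpy())
    wt = wt.iloc[:, order]
    tg = tg.iloc[:, order]
    names = list(wt.columns)
    m = len(names)
    n_wt, n_tg = wt.shape[0], tg.shape[0]
    iu = np.triu_indices(m, k=1)

    r_wt = np.clip(np.corrcoef(wt.to_numpy(), rowvar=False), -1.0, 1.0)[iu]
    r_tg = np.clip(np.corrcoef(tg.to_numpy(), rowvar=False), -1.0, 1.0)[iu]
    p_wt = _p_matrix(r_wt, n_wt)
    p_tg = _p_matrix(r_tg, n_tg)
    cls_wt = _classify_matrix(r_wt, p_wt, config)
    cls_tg = _classify_matrix(r_tg, p_tg, config)

    strong_wt = (cls_wt == _STRONG_POS) | (cls_wt == _STRONG_NEG)
    strong_tg = (cls_tg == _STRONG_POS) | (cls_tg == _STRONG_NEG)
    candidate = (strong_wt & (cls_tg == _WEAK)) | (strong_tg & (cls_wt == _WEAK))

    counts = {
        "wt_strong": int(strong_wt.sum()),
        "tg_strong": int(strong_tg.sum()),
        "shared_strong": int((strong_wt & strong_tg).sum()),
        "total": m * (m - 1) // 2,
    }

    wt_arr, tg_arr = wt.to_numpy(), tg.to_numpy()
    results: list[DiffCorrelationResult] = []
    records: list[CorrelationRecord] = []
    cand_p_fisher: list[float] = []
    for k in np.flatnonzero(candidate):
        i, j = int(iu[0][k]), int(iu[1][k])
        pair = (names[i], names[j])
        clamped = bool(abs(r_wt[k]) >= _CLAMP or abs(r_tg[k]) >= _CLAMP)
        records.append(
            CorrelationRecord(
                metabolite_a=pair[0],
                metabolite_b=pair[1],
                r_wt=float(r_wt[k]),
                r_tg=float(r_tg[k]),
                p_wt=float(p_wt[k]),
                p_tg=float(p_tg[k]),
                n_wt=n_wt,
                n_tg=n_tg,
                class_wt=_CODE_TO_CLASS[int(cls_wt[k])],
                class_tg=_CODE_TO_CLASS[int(cls_tg[k])],
                clamped=clamped,
            )
        )
        jk_pass, jk_r = jackknife_validate(
            pair, wt_arr[:, [i, j]], tg_arr[:, [i, j]], config
        )
        z_stat, p_fisher = fisher_r_to_z_test(float(r_wt[k]), n_wt, float(r_tg[k]), n_tg)
        cand_p_fisher.append(p_fisher)
        results.append(
            DiffCorrelationResult(
                pair=pair,
                candidate=True,
                jackknife_pass=jk_pass,
                z_wt=float(np.arctanh(np.clip(r_wt[k], -_CLAMP, _CLAMP))),
                z_tg=float(np.arctanh(np.clip(r_tg[k], -_CLAMP, _CLAMP))),
                z_stat=z_stat,
                p_fisher=p_fisher,
                altered=False,  # set below
                strong_group="wt" if strong_wt[k] else "tg",
                jackknife_r=jk_r,
            )
        )

    # optional BH across candidate pairs (off by default: the reference
    # procedure applies no multiplicity correction to the Fisher p-values)
    if config.fisher_fdr_across_pairs and cand_p_fisher:
        from .abundance import adjust_fdr

        adj = adjust_fdr(cand_p_fisher)
        for res, p_adj in zip(results, adj):
            res.altered = bool(res.jackknife_pass and p_adj < config.fisher_alpha)
    else:
        for res in results:
            res.altered = bool(res.jackknife_pass and res.p_fisher < config.fisher_alpha)

    nodes = detect_nodes(results)

    pair_frame = scatter = None
    if collect_pairs:
        pair_frame = pd.DataFrame(
            {
                "metabolite_a": [names[i] for i in iu[0]],
                "metabolite_b": [names[j] for j in iu[1]],
                "r_wt": r_wt,
                "r_tg": r_tg,
                "p_wt": p_wt,
                "p_tg": p_tg,
                "class_wt": [_CODE_TO_CLASS[int(c)].value for c in cls_wt],
                "class_tg": [_CODE_TO_CLASS[int(c)].value for c in cls_tg],
                "candidate": candidate,
            }
        )
        scatter = _scatter_frame(wt, tg, [r.pair for r in results if r.altered])
    return DiffCorrOutput(
        results=results,
        records=records,
        counts=counts,
        nodes=nodes,
        pair_frame=pair_frame,
        scatter=scatter,
    )


def _scatter_frame(wt: pd.DataFrame, tg: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Plot-ready per-sample values for altered pairs (one row per sample)."""
    rows = []
    for a, b in pairs:
        pair_id = f"{a}__{b}"
        for group, df in (("wt", wt), ("tg", tg)):
            for animal, row in df[[a, b]].iterrows():
                rows.append(
                    {"pair_id": pair_id, "group": group, "sample": animal, "x": row[a], "y": row[b]}
                )
    return pd.DataFrame(rows, columns=["pair_id", "group", "sample", "x", "y"])


def diffcorr_frame(results: list[DiffCorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite_a": r.pair[0],
                "metabolite_b": r.pair[1],
                "candidate": r.candidate,
                "strong_group": r.strong_group,
                "jackknife_pass": r.jackknife_pass,
                "z_wt": r.z_wt,
                "z_tg": r.z_tg,
                "z_stat": r.z_stat,
                "p_fisher": r.p_fisher,
                "altered": r.altered,
            }
            for r in results
        ]
    )
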