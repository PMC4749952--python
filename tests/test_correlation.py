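import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import LEVERAGE_X, LEVERAGE_Y, WEAK_X, WEAK_Y, averaged_group_matrices, planted_pair_config
from diffmet import correlation, simulate
from diffmet.config import RunConfig
from diffmet.correlation import (
    classify_correlation,
    correlation_p,
    count_strong_pairs,
    detect_nodes,
    enumerate_pairs,
    fisher_r_to_z_test,
    find_candidates,
    jackknife_validate,
    pearson_r,
    run_diffcorr,
)
from diffmet.types import CorrelationClass, CorrelationRecord, DiffCorrelationResult


class TestPearsonR:
    def test_exact_linearity(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computation(self):
        # centered cross-product 14.5, each sum of squares 17.5: r = 14.5/17.5
        assert pearson_r([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5]) == pytest.approx(14.5 / 17.5, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            n = int(rng.integers(4, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert pearson_r(2.5 * x + 1, y) == pytest.approx(pearson_r(x, y), abs=1e-12)
        assert pearson_r(y, x) == pytest.approx(pearson_r(x, y), abs=1e-12)


class TestCorrelationP:
    def test_reference_points(self):
        assert correlation_p(0.0, 10) == 1.0
        assert correlation_p(0.9, 6) == pytest.approx(0.0145, abs=2e-4)
        assert correlation_p(-0.9, 6) == correlation_p(0.9, 6)
        assert correlation_p(1.0, 6) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            correlation_p(0.5, 3)

    def test_matches_scipy_p_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r = pearson_r(x, y)
            assert correlation_p(r, n) == pytest.approx(stats.pearsonr(x, y).pvalue, abs=1e-10)


class TestClassifyCorrelation:
    @pytest.mark.parametrize(
        "r,p,expected",
        [
            (0.95, 0.01, CorrelationClass.STRONG_POS),
            (-0.95, 0.01, CorrelationClass.STRONG_NEG),
            (0.05, 0.9, CorrelationClass.WEAK),
            (0.5, 0.3, CorrelationClass.INTERMEDIATE),
            (0.95, 0.2, CorrelationClass.INTERMEDIATE),  # strong r but insignificant
            (0.05, 0.01, CorrelationClass.INTERMEDIATE),  # small r but significant
        ],
    )
    def test_threshold_rules(self, r, p, expected):
        assert classify_correlation(r, p) is expected

    def test_idempotent_reclassification(self):
        rng = np.random.default_rng(9)
        cfg = RunConfig()
        for _ in range(200):
            r = float(rng.uniform(-1, 1))
            p = float(rng.uniform(0, 1))
            c1 = classify_correlation(r, p, cfg)
            assert classify_correlation(r, p, cfg) is c1


class TestEnumeratePairs:
    @pytest.mark.parametrize("m,expected", [(51, 1275), (37, 666), (2, 1)])
    def test_pair_counts(self, m, expected):
        pairs = enumerate_pairs([f"m{i:03d}" for i in range(m)])
        assert len(pairs) == expected
        assert all(a < b for a, b in pairs)
        assert len(set(pairs)) == len(pairs)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs(["a", "b", "a"])


class TestFisherRToZ:
    def test_equal_correlations_null(self):
        z, p = fisher_r_to_z_test(0.5, 6, 0.5, 6)
        assert z == 0.0 and p == 1.0

    def test_reference_value(self):
        z, p = fisher_r_to_z_test(0.95, 6, 0.05, 6)
        assert z == pytest.approx(2.182, abs=1e-3)
        assert p == pytest.approx(0.0291, abs=1e-3)

    def test_antisymmetry(self):
        z1, p1 = fisher_r_to_z_test(0.95, 6, 0.05, 8)
        z2, p2 = fisher_r_to_z_test(0.05, 8, 0.95, 6)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_standard_error_exact_at_n6(self):
        # 1/(6-3) + 1/(6-3) = 2/3
        z, _ = fisher_r_to_z_test(np.tanh(1.0), 6, 0.0, 6)
        assert z == pytest.approx(1.0 / np.sqrt(2.0 / 3.0), abs=1e-9)

    def test_degenerate_r_clamped_finite(self):
        z, p = fisher_r_to_z_test(1.0, 6, 0.0, 6)
        assert np.isfinite(z) and 0 < p <= 1

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_r_to_z_test(0.5, 3, 0.5, 6)


class TestFindCandidates:
    def _record(self, r_wt, p_wt, r_tg, p_tg):
        cfg = RunConfig()
        return CorrelationRecord(
            metabolite_a="a",
            metabolite_b="b",
            r_wt=r_wt,
            r_tg=r_tg,
            p_wt=p_wt,
            p_tg=p_tg,
            n_wt=6,
            n_tg=6,
            class_wt=classify_correlation(r_wt, p_wt, cfg),
            class_tg=classify_correlation(r_tg, p_tg, cfg),
        )

    def test_strong_weak_is_candidate(self):
        rec = self._record(0.02, 0.96, 0.97, 0.001)
        assert find_candidates([rec]) == [rec]

    def test_strong_both_is_not(self):
        assert find_candidates([self._record(0.97, 0.001, 0.97, 0.001)]) == []

    def test_intermediate_other_side_is_not(self):
        assert find_candidates([self._record(0.5, 0.3, 0.97, 0.001)]) == []


class TestJackknifeValidate:
    def test_perfect_correlation_survives_any_deletion(self):
        tg = np.column_stack([np.arange(6.0), np.arange(6.0)])  # exact y = x
        wt = np.column_stack([WEAK_X, WEAK_Y])
        passed, per_group = jackknife_validate(("a", "b"), wt, tg, RunConfig())
        assert passed
        assert all(r == pytest.approx(1.0) for r in per_group["tg"])
        assert all(abs(r) < 0.2 for r in per_group["wt"])

    def test_leverage_point_fails(self):
        """r = 0.99 driven by one sample fails once that sample is removed."""
        tg = np.column_stack([LEVERAGE_X, LEVERAGE_Y])
        wt = np.column_stack([WEAK_X, WEAK_Y])
        full_r = pearson_r(LEVERAGE_X, LEVERAGE_Y)
        assert full_r > 0.9
        r_without = pearson_r(LEVERAGE_X[:-1], LEVERAGE_Y[:-1])
        assert r_without < 0.7
        passed, per_group = jackknife_validate(("a", "b"), wt, tg, RunConfig())
        assert not passed
        assert per_group["tg"][-1] == pytest.approx(r_without, abs=1e-12)

    def test_ordering_invariance(self):
        rng = np.random.default_rng(14)
        tg = np.column_stack([np.arange(6.0), np.arange(6.0) + rng.normal(0, 0.01, 6)])
        wt = np.column_stack([WEAK_X, WEAK_Y])
        passed, _ = jackknife_validate(("a", "b"), wt, tg, RunConfig())
        perm = rng.permutation(6)
        passed_perm, _ = jackknife_validate(("a", "b"), wt[perm], tg[perm], RunConfig())
        assert passed == passed_perm

    def test_small_group_rejected(self):
        tg = np.column_stack([np.arange(4.0), np.arange(4.0)])
        wt = np.column_stack([WEAK_X, WEAK_Y])
        with pytest.raises(ValueError, match="5"):
            jackknife_validate(("a", "b"), wt, tg, RunConfig())

    def test_equals_exhaustive_joint_deletion_oracle(self):
        """Independent per-group leave-one-out decides identically to the
        paired reading that deletes one sample from each group jointly."""
        cfg = RunConfig()
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 20:
            lam = rng.uniform(0.9, 1.0)
            f = rng.normal(size=6)
            tg = np.column_stack(
                [lam * f + np.sqrt(1 - lam**2) * rng.normal(size=6) for _ in range(2)]
            )
            wt = rng.normal(size=(6, 2))
            try:
                passed, _ = jackknife_validate(("a", "b"), wt, tg, cfg)
            except ValueError:
                continue  # not a candidate
            checked += 1
            r_wt = pearson_r(wt[:, 0], wt[:, 1])
            strong_arr, weak_arr = (wt, tg) if abs(r_wt) > 0.9 else (tg, wt)
            sign = np.sign(pearson_r(strong_arr[:, 0], strong_arr[:, 1]))
            oracle = True
            for i_s, i_w in itertools.product(range(6), range(6)):
                s_sub = np.delete(strong_arr, i_s, axis=0)
                w_sub = np.delete(weak_arr, i_w, axis=0)
                r_s = pearson_r(s_sub[:, 0], s_sub[:, 1])
                r_w = pearson_r(w_sub[:, 0], w_sub[:, 1])
                if not (
                    sign * r_s > cfg.jackknife_strong_threshold
                    and correlation_p(r_s, 5) < 0.05
                    and abs(r_w) < cfg.jackknife_weak_threshold
                ):
                    oracle = False
                    break
            assert passed == oracle


class TestDetectNodes:
    def _altered(self, a, b):
        return DiffCorrelationResult(
            pair=(a, b), candidate=True, jackknife_pass=True,
            z_wt=0.0, z_tg=2.0, z_stat=2.5, p_fisher=0.01, altered=True,
        )

    def test_hub_degree(self):
        altered = [self._altered("cys", "asn"), self._altered("cys", "pro"), self._altered("cys", "val")]
        assert detect_nodes(altered) == {"cys": 3}

    def test_disjoint_pairs_no_nodes(self):
        altered = [self._altered("a", "b"), self._altered("c", "d")]
        assert detect_nodes(altered) == {}

    def test_matches_brute_force_incidence(self):
        rng = np.random.default_rng(31)
        mets = [f"m{i}" for i in range(8)]
        for _ in range(20):
            pairs = [tuple(sorted(rng.choice(mets, 2, replace=False))) for _ in range(6)]
            pairs = list(dict.fromkeys(pairs))
            altered = [self._altered(a, b) for a, b in pairs]
            nodes = detect_nodes(altered)
            for met in mets:
                deg = sum(met in p for p in pairs)
                assert (nodes.get(met, 0) == deg) or (deg < 2 and met not in nodes)


class TestCountStrongPairs:
    def test_identity_groups(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(rng.normal(size=(6, 10)), columns=[f"m{i}" for i in range(10)])
        counts = count_strong_pairs(df, df)
        assert counts["wt_strong"] == counts["tg_strong"] == counts["shared_strong"]
        assert counts["total"] == 45

    def test_planted_pairs_are_shared(self):
        # near-unit loading with small technical noise forces r ~ 1 in both
        # groups so the planted pairs must appear in the shared count
        cfg = simulate.SyntheticConfig(
            tissues=("cerebellum",),
            n_metabolites={"cerebellum": 20},
            correlation_plan=tuple(
                simulate.PlantedPair("cerebellum", (2 * k, 2 * k + 1), "both", 0.998)
                for k in range(3)
            ),
            technical_sd=0.002,
            seed=5,
        )
        metadata, table, _ = simulate.generate_cohort(cfg)
        wt, tg = averaged_group_matrices(metadata, table, "cerebellum")
        counts = count_strong_pairs(wt, tg)
        assert counts["shared_strong"] >= 3
        assert counts["shared_strong"] <= min(counts["wt_strong"], counts["tg_strong"])

    def test_matches_brute_force_double_loop(self):
        cfg = RunConfig()
        rng = np.random.default_rng(41)
        for trial in range(15):
            n, m = 6, 8
            wt = pd.DataFrame(rng.normal(size=(n, m)), columns=[f"m{i}" for i in range(m)])
            tg = pd.DataFrame(rng.normal(size=(n, m)), columns=[f"m{i}" for i in range(m)])
            counts = count_strong_pairs(wt, tg, cfg)
            brute = {"wt": 0, "tg": 0, "shared": 0}
            for i in range(m):
                for j in range(i + 1, m):
                    strongs = {}
                    for g, df in (("wt", wt), ("tg", tg)):
                        r = pearson_r(df.iloc[:, i], df.iloc[:, j])
                        p = correlation_p(r, n)
                        strongs[g] = classify_correlation(r, p, cfg) in (
                            CorrelationClass.STRONG_POS,
                            CorrelationClass.STRONG_NEG,
                        )
                        brute[g] += strongs[g]
                    brute["shared"] += strongs["wt"] and strongs["tg"]
            assert counts["wt_strong"] == brute["wt"]
            assert counts["tg_strong"] == brute["tg"]
            assert counts["shared_strong"] == brute["shared"]

    def test_mismatched_metabolite_sets_rejected(self):
        rng = np.random.default_rng(1)
        wt = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        tg = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "d"])
        with pytest.raises(ValueError):
            count_strong_pairs(wt, tg)


class TestRunDiffcorr:
    def test_gate_inclusions_and_counts(self):
        cfg = planted_pair_config(seed=2, m=30)
        metadata, table, _ = simulate.generate_cohort(cfg)
        wt, tg = averaged_group_matrices(metadata, table, "cerebellum")
        out = run_diffcorr(wt, tg)
        assert out.counts["total"] == 30 * 29 // 2
        assert out.counts["shared_strong"] <= min(out.counts["wt_strong"], out.counts["tg_strong"])
        altered = {r.pair for r in out.altered}
        jk = {r.pair for r in out.results if r.jackknife_pass}
        cand = {r.pair for r in out.results}
        assert altered <= jk <= cand
        assert len(out.pair_frame) == out.counts["total"]
        for r in out.results:  # altered only via all three gates
            if r.altered:
                assert r.candidate and r.jackknife_pass and r.p_fisher < cfg_alpha()

    def test_group_swap_preserves_altered_set(self):
        cfg = planted_pair_config(seed=6, m=25)
        metadata, table, _ = simulate.generate_cohort(cfg)
        wt, tg = averaged_group_matrices(metadata, table, "cerebellum")
        out = run_diffcorr(wt, tg)
        out_swapped = run_diffcorr(tg, wt)
        assert {r.pair for r in out.altered} == {r.pair for r in out_swapped.altered}
        for a, b in zip(out.results, out_swapped.results):
            assert a.z_stat == pytest.approx(-b.z_stat, abs=1e-12)

    def test_scatter_export_covers_altered_pairs(self):
        # planted pair forced through the gate by construction: near-exact
        # transgenic line, frozen weak wild-type values
        rng = np.random.default_rng(3)
        m = 6
        wt = pd.DataFrame(rng.normal(size=(6, m)), columns=[f"m{i}" for i in range(m)])
        tg = pd.DataFrame(rng.normal(size=(6, m)), columns=[f"m{i}" for i in range(m)])
        wt["m0"], wt["m1"] = WEAK_X, WEAK_Y
        line = np.arange(6.0)
        tg["m0"], tg["m1"] = line, line + rng.normal(0, 1e-3, 6)
        out = run_diffcorr(wt, tg)
        assert ("m0", "m1") in {r.pair for r in out.altered}
        scat = out.scatter
        pair_rows = scat[scat.pair_id == "m0__m1"]
        assert len(pair_rows) == 12  # 6 samples x 2 groups
        assert set(pair_rows.group) == {"wt", "tg"}


def cfg_alpha() -> float:
    return RunConfig().fisher_alpha
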