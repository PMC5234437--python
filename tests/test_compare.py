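"""Filter cascade, nonparametric test primitives and serial comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from otukit.compare import (
    FilterConfig,
    apply_abundance_cutoff,
    median_gate,
    prevalence_gate,
    serial_comparison,
    zeros_to_missing,
)
from otukit.stats import bh_adjust, fisher_prevalence, kruskal_wallis, mann_whitney
from tests.conftest import make_mapping, make_rel


class TestCutoffAndMasking:
    def test_cutoff_boundary_is_inclusive(self):
        rel = make_rel({"s": [0.4, 0.5, 99.1]}, index=["a", "b", "c"])
        out = apply_abundance_cutoff(rel, 0.5)
        assert out.values.loc["a", "s"] == 0.0  # below threshold -> absent
        assert out.values.loc["b", "s"] == 0.5  # at threshold -> kept
        assert out.values.loc["c", "s"] == 99.1

    def test_zero_cutoff_is_identity(self):
        rel = make_rel({"s": [0.01, 99.99]}, index=["a", "b"])
        out = apply_abundance_cutoff(rel, 0.0)
        pd.testing.assert_frame_equal(out.values, rel.values)

    def test_zeros_become_missing(self):
        df = pd.DataFrame({"s1": [0.0, 1.2], "s2": [0.0, 3.4]}, index=["a", "b"])
        masked = zeros_to_missing(df)
        assert masked.loc["a"].isna().all()
        assert masked.loc["b"].notna().sum() == 2


class TestGates:
    def _values(self, detections_g1: int, detections_g2: int, n: int = 10):
        cols = [f"g1_{i}" for i in range(n)] + [f"g2_{i}" for i in range(n)]
        row = [2.0] * detections_g1 + [np.nan] * (n - detections_g1)
        row += [2.0] * detections_g2 + [np.nan] * (n - detections_g2)
        values = pd.DataFrame([row], index=["v"], columns=cols)
        groups = pd.Series(["G1"] * n + ["G2"] * n, index=cols)
        return values, groups

    def test_four_of_ten_is_tested(self):
        values, groups = self._values(4, 0)
        tested, skipped, prev = prevalence_gate(values, groups, 0.30)
        assert tested == ["v"]
        assert prev.loc["v", "G1"] == 4

    def test_three_of_ten_in_both_groups_is_skipped(self):
        values, groups = self._values(3, 3)
        tested, skipped, _ = prevalence_gate(values, groups, 0.30)
        assert skipped == ["v"]  # 0.30 is not strictly above 0.30

    def test_zero_prevalence_min_tests_any_detection(self):
        values, groups = self._values(1, 0)
        tested, _, _ = prevalence_gate(values, groups, 0.0)
        assert tested == ["v"]

    def test_median_gate_boundaries(self):
        cols = [f"g1_{i}" for i in range(3)] + [f"g2_{i}" for i in range(3)]
        groups = pd.Series(["G1"] * 3 + ["G2"] * 3, index=cols)
        low = pd.DataFrame([[0.25] * 3 + [0.70] * 3], index=["v"], columns=cols)
        tested, skipped, _ = median_gate(low, groups, 1.0)
        assert skipped == ["v"]  # medians 0.25 / 0.70 both below 1%
        high = pd.DataFrame([[0.8] * 3 + [1.2] * 3], index=["v"], columns=cols)
        tested, _, _ = median_gate(high, groups, 1.0)
        assert tested == ["v"]
        tested, _, _ = median_gate(low, groups, 0.0)
        assert tested == ["v"]

    def test_gate_monotonicity(self):
        rng = np.random.default_rng(2)
        cols = [f"s{i}" for i in range(20)]
        values = pd.DataFrame(
            np.where(rng.random((30, 20)) < 0.5, rng.random((30, 20)) * 4, np.nan),
            index=[f"v{i}" for i in range(30)], columns=cols,
        )
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=cols)
        prev_sizes = [len(prevalence_gate(values, groups, p)[0])
                      for p in (0.0, 0.2, 0.4, 0.6)]
        assert prev_sizes == sorted(prev_sizes, reverse=True)
        med_sizes = [len(median_gate(values, groups, m)[0]) for m in (0.0, 1.0, 2.0)]
        assert med_sizes == sorted(med_sizes, reverse=True)


class TestExactTests:
    def test_kruskal_wallis_hand_value(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7, rel=1e-12)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_kruskal_wallis_identical_groups(self):
        assert kruskal_wallis([[2, 2], [2, 2, 2]]) == (0.0, 1.0)

    def test_kw_matches_mw_asymptotically_for_two_groups(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(50), rng.standard_normal(50) + 0.3
        _, p_kw = kruskal_wallis([a, b])
        import scipy.stats as sps

        p_mw = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=False).pvalue
        assert p_kw == pytest.approx(p_mw, rel=1e-6)

    def test_mann_whitney_exact_enumeration(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, rel=1e-12)  # 2 / C(6,3)

    def test_mann_whitney_symmetry_and_identity(self):
        _, p1 = mann_whitney([1, 5, 9], [2, 4, 8])
        _, p2 = mann_whitney([2, 4, 8], [1, 5, 9])
        assert p1 == p2
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_mann_whitney_exact_matches_enumeration_small_n(self):
        rng = np.random.default_rng(1)
        for n_a, n_b in [(3, 3), (4, 5), (6, 6)]:
            pooled = rng.permutation(rng.standard_normal(n_a + n_b))
            a, b = pooled[:n_a], pooled[n_a:]
            _, p = mann_whitney(a, b)
            # enumeration oracle over all rank splits
            import scipy.stats as sps

            u_obs = sps.mannwhitneyu(a, b).statistic
            u_min = min(u_obs, n_a * n_b - u_obs)
            hits = total = 0
            for combo in itertools.combinations(range(n_a + n_b), n_a):
                ranks_a = sum(combo) + n_a  # 1-based rank sum
                u = ranks_a - n_a * (n_a + 1) / 2
                total += 1
                if min(u, n_a * n_b - u) <= u_min + 1e-12:
                    hits += 1
            assert p == pytest.approx(hits / total, rel=1e-9)

    def test_fisher_disjoint_prevalence(self):
        res = fisher_prevalence([0, 5], [5, 5])
        assert res.p == pytest.approx(2 / 252, rel=1e-9)

    def test_fisher_equal_prevalence_and_symmetry(self):
        assert fisher_prevalence([3, 3], [10, 10]).p == pytest.approx(1.0)
        p1 = fisher_prevalence([2, 7], [10, 10]).p
        p2 = fisher_prevalence([7, 2], [10, 10]).p
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_fisher_2xk_matches_r_reference_value(self):
        # fisher.test(matrix(c(0,5,2, 5,0,3), nrow=2)) in R gives 0.009324009
        res = fisher_prevalence([0, 5, 2], [5, 5, 5])
        assert res.method == "exact-2xk"
        assert res.p == pytest.approx(0.009324009, rel=1e-6)

    def test_fisher_monte_carlo_close_to_exact(self):
        exact = fisher_prevalence([2, 9, 5], [12, 12, 12]).p
        mc = fisher_prevalence([2, 9, 5], [12, 12, 12], exact_n_max=10, seed=0)
        assert mc.method == "monte-carlo"
        assert mc.se is not None
        assert mc.p == pytest.approx(exact, abs=4 * mc.se + 1e-3)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_step_up_hand_value(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_missing_pass_through(self):
        out = bh_adjust([0.04, np.nan, 0.5])
        np.testing.assert_allclose(out[[0, 2]], [0.08, 0.5])
        assert np.isnan(out[1])

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.random(30)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def _disjoint_presence_dataset():
    """Three OTUs, each elevated in a disjoint subset of diseased samples.

    With zeros kept as values the disease/healthy comparison is washed out;
    masking zeros as missing reveals that each OTU, where present, sits at a
    higher level in diseased samples.
    """
    n = 12
    cols = [f"dis_{i}" for i in range(n)] + [f"hea_{i}" for i in range(n)]
    rows = {}
    high = [5.0, 6.0, 7.0, 8.0]
    low = [1.0, 1.2, 1.5, 2.0]
    for k in range(3):
        dis = [0.0] * n
        for j, v in enumerate(high):
            dis[4 * k + j] = v
        hea = [0.0] * n
        for j, v in enumerate(low):
            hea[4 * k + j] = v
        rows[f"OTU_{k + 1}"] = dis + hea
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.columns = cols
    groups = pd.Series(["diseased"] * n + ["healthy"] * n, index=cols)
    return values, groups


class TestZeroMaskingEffect:
    def test_masking_reveals_disjoint_presence_signal(self):
        values, groups = _disjoint_presence_dataset()
        dis_cols = groups.index[groups == "diseased"]
        hea_cols = groups.index[groups == "healthy"]
        for otu in values.index:
            a_raw = values.loc[otu, dis_cols].to_numpy()
            b_raw = values.loc[otu, hea_cols].to_numpy()
            _, p_retained = mann_whitney(a_raw, b_raw)
            masked = zeros_to_missing(values)
            a = masked.loc[otu, dis_cols].dropna().to_numpy()
            b = masked.loc[otu, hea_cols].dropna().to_numpy()
            _, p_masked = mann_whitney(a, b)
            assert p_retained > p_masked
            assert p_retained > 0.05
            assert p_masked < 0.05
            assert np.median(a) > np.median(b)


class TestSerialComparison:
    def _dataset(self, rng, n_per_group=10, n_vars=30, effect_var=None, fold=4.0):
        cols = [f"A{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)]
        base = rng.dirichlet(np.full(n_vars, 2.0))
        values = np.empty((n_vars, 2 * n_per_group))
        for j in range(2 * n_per_group):
            mean = base.copy()
            if effect_var is not None and j >= n_per_group:
                mean[effect_var] *= fold
                mean = mean / mean.sum()
            values[:, j] = 100 * rng.dirichlet(50 * mean)
        rel = make_rel({c: values[:, j] for j, c in enumerate(cols)},
                       index=[f"v{i}" for i in range(n_vars)])
        mapping = make_mapping({c: ("A" if c.startswith("A") else "B") for c in cols})
        return rel, mapping

    def test_planted_effect_has_smallest_adjusted_p(self):
        rng = np.random.default_rng(7)
        rel, mapping = self._dataset(rng, effect_var=0, fold=6.0)
        res = serial_comparison(rel, mapping, "Group", FilterConfig(), seed=0)
        tested = res.records[res.records["tested"]]
        assert tested["kw_p_adj"].idxmin() == "v0"

    def test_disabled_gates_test_everything_detected(self):
        rng = np.random.default_rng(8)
        rel, mapping = self._dataset(rng)
        config = FilterConfig(abundance_cutoff=0.0, prevalence_min=0.0, median_min=0.0)
        res = serial_comparison(rel, mapping, "Group", config, seed=0)
        assert res.records["tested"].all()

    def test_two_groups_single_pairwise_test_per_variable(self):
        rng = np.random.default_rng(9)
        rel, mapping = self._dataset(rng)
        res = serial_comparison(rel, mapping, "Group", FilterConfig(), seed=0)
        tested = res.records.index[res.records["tested"]]
        assert set(res.pairwise["variable"]) == set(tested)
        assert res.pairwise.groupby("variable").size().eq(1).all()

    def test_skip_reasons_recorded(self):
        cols = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
        sparse = [3.0] * 2 + [0.0] * 8 + [3.0] * 2 + [0.0] * 8  # 2/10 in each group
        low = [0.6] * 10 + [0.7] * 10  # detected everywhere, medians below 1%
        strong = [5.0] * 10 + [9.0] * 10
        rel = make_rel({c: [sparse[i], low[i], strong[i]] for i, c in enumerate(cols)},
                       index=["sparse", "low", "strong"])
        mapping = make_mapping({c: c[0] for c in cols})
        res = serial_comparison(rel, mapping, "Group", FilterConfig(), seed=0)
        assert res.records.loc["sparse", "skip_reason"] == "prevalence"
        assert res.records.loc["low", "skip_reason"] == "median"
        assert res.records.loc["strong", "tested"]

    def test_meta_variables_bypass_gates(self):
        rng = np.random.default_rng(10)
        rel, mapping = self._dataset(rng, n_vars=5)
        cols = list(rel.values.columns)
        meta = pd.DataFrame(
            {c: [0.01 * (i + 1)] for i, c in enumerate(cols)}, index=["tiny_meta"]
        )
        res = serial_comparison(rel, mapping, "Group", FilterConfig(), meta=meta, seed=0)
        # far below every gate, but meta-variables are tested regardless
        assert res.records.loc["tiny_meta", "tested"]
        assert res.records.loc["tiny_meta", "class"] == "meta"


class TestNullCalibration:
    def test_kw_type_one_error_on_null_data(self):
        # 2 groups x 15 samples, 200 variables, 300 reps of pure noise
        rng = np.random.default_rng(123)
        n_reps, n_vars = 300, 200
        raw = np.empty(n_reps * n_vars)
        k = 0
        for _ in range(n_reps):
            data = rng.standard_normal((n_vars, 30))
            for v in range(n_vars):
                _, raw[k] = kruskal_wallis([data[v, :15], data[v, 15:]])
                k += 1
        rate = (raw < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(raw))
        assert abs(rate - 0.05) < 3 * se
        adj_rates = []
        for r in range(n_reps):
            adj = bh_adjust(raw[r * n_vars:(r + 1) * n_vars])
            adj_rates.append((adj < 0.05).mean())
        assert np.mean(adj_rates) <= 0.05
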