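"""Nonparametric statistics and stratified report sections."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fracloc.strata import (
    StatError,
    bh_adjust,
    feature_correlations,
    group_compare,
    length_bin_analysis,
    length_controlled_exon_analysis,
    mann_whitney_u,
    spearman,
)


def _permutation_mww_oracle(x, y):
    """Brute-force two-sided p: enumerate all label assignments, recompute U."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(a, b):
        return sum(1 for xi in a for yi in b if xi > yi) + 0.5 * sum(
            1 for xi in a for yi in b if xi == yi
        )

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(a, b))
    us = np.array(us)
    lower = (us <= u_obs + 1e-9).mean()
    upper = (us >= u_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(lower, upper))


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = np.arange(10.0)
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_monotone_decreasing_is_minus_one(self):
        x = np.arange(10.0)
        rho, _ = spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_four_point_worked_example(self):
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(StatError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_scipy_on_large_samples(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), y)
        rho3, _ = spearman(x, y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert rho1 == pytest.approx(rho3, abs=1e-12)


class TestMannWhitney:
    def test_identical_samples_have_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = mann_whitney_u(x, x)
        assert p > 0.9

    def test_fully_separated_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_exact_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(1.0, 10.0))[:4]
        y = np.setdiff1d(np.arange(1.0, 10.0), x)[:5]
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(_permutation_mww_oracle(x, y), abs=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pool = rng.permutation(np.arange(12.0))
            x, y = pool[:5], pool[5:]
            _, p = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approximation_close_to_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 6, size=30).astype(float)
        y = rng.integers(1, 7, size=25).astype(float)
        _, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(StatError):
            mann_whitney_u([], [1.0])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_step_up_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(StatError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_contract_bounds_and_rank_monotonicity(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert ((q >= p - 1e-12) & (q <= 1.0 + 1e-12)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_fdr_control_on_uniform_null(self):
        """Average false-discovery proportion at level 0.05 stays <= 0.05."""
        rng = np.random.default_rng(6)
        fdp = []
        for _ in range(1000):
            p = rng.uniform(size=20)
            fdp.append((bh_adjust(p) < 0.05).mean())
        assert np.mean(fdp) <= 0.05


class TestReportSections:
    def test_delta_equal_to_length_has_rho_one(self, metrics2000):
        loc = pd.DataFrame(
            {"delta_shrunk": metrics2000["pre_mrna_length"].astype(float)},
            index=metrics2000.index,
        )
        fc = feature_correlations(loc, metrics2000)
        row = fc.set_index("metric").loc["pre_mrna_length"]
        assert row["rho"] == pytest.approx(1.0)

    def test_identical_groups_not_significant(self):
        vals = np.tile(np.arange(20.0), 2)
        loc = pd.DataFrame({"delta_shrunk": vals},
                           index=[f"g{i}" for i in range(40)])
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=loc.index)
        rep = group_compare(loc, labels)
        assert (rep.sections["group_tests"]["q"] > 0.9).all()

    def test_mapping_and_series_groupings_agree(self):
        rng = np.random.default_rng(7)
        loc = pd.DataFrame({"delta_shrunk": rng.normal(size=30)},
                           index=[f"g{i}" for i in range(30)])
        labels = pd.Series(["A"] * 10 + ["B"] * 20, index=loc.index)
        r1 = group_compare(loc, labels)
        r2 = group_compare(loc, labels.to_dict())
        pd.testing.assert_frame_equal(r1.sections["group_tests"],
                                      r2.sections["group_tests"])

    def test_small_group_excluded_with_warning(self):
        loc = pd.DataFrame({"delta_shrunk": np.arange(11.0)},
                           index=[f"g{i}" for i in range(11)])
        labels = pd.Series(["A"] * 5 + ["B"] * 5 + ["C"], index=loc.index)
        with pytest.warns(UserWarning, match="C"):
            rep = group_compare(loc, labels)
        assert set(rep.sections["group_summaries"]["group"]) == {"A", "B"}

    def test_single_occupied_bin_yields_no_tests(self):
        loc = pd.DataFrame({"delta_shrunk": np.arange(10.0)},
                           index=[f"g{i}" for i in range(10)])
        gm = pd.DataFrame({"pre_mrna_length": [5000.0] * 10}, index=loc.index)
        rep = length_bin_analysis(loc, gm)
        assert len(rep.sections["length_bin_tests"]) == 0
        summaries = rep.sections["length_bin_summaries"].set_index("bin")
        assert summaries.loc["<10 kb", "n"] == 10
        assert summaries.loc["20-30 kb", "n"] == 0

    def test_empty_window_summarized_without_crash(self):
        loc = pd.DataFrame({"delta_shrunk": np.arange(20.0)},
                           index=[f"g{i}" for i in range(20)])
        gm = pd.DataFrame(
            {"pre_mrna_length": [22_000.0] * 20,
             "rounded_exon_count": [2] * 10 + [5] * 10},
            index=loc.index,
        )
        rep = length_controlled_exon_analysis(loc, gm)
        summ = rep.sections["exon_window_summaries"]
        assert (summ["window"] == "20-25 kb").all()
        tests = rep.sections["exon_window_tests"]
        assert (tests["kind"] == "within_window").all()

    def test_report_serialization_is_deterministic(self, tmp_path):
        rng = np.random.default_rng(8)
        loc = pd.DataFrame({"delta_shrunk": rng.normal(size=50)},
                           index=[f"g{i}" for i in range(50)])
        labels = pd.Series(["A"] * 25 + ["B"] * 25, index=loc.index)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        group_compare(loc, labels).to_tsv(d1)
        group_compare(loc, labels).to_tsv(d2)
        for f1, f2 in zip(sorted(d1.iterdir()), sorted(d2.iterdir())):
            assert f1.read_bytes() == f2.read_bytes()


class TestSyntheticEffects:
    def test_default_effect_gives_negative_length_correlation(self, default_fit, metrics2000):
        _, _, res = default_fit
        fc = feature_correlations(res.table, metrics2000)
        row = fc.set_index("metric").loc["pre_mrna_length"]
        assert row["rho"] < 0
        assert row["p"] < 1e-10

    def test_length_bin_medians_decrease_with_length(self, default_fit, metrics2000):
        _, _, res = default_fit
        rep = length_bin_analysis(res.table, metrics2000)
        med = rep.sections["length_bin_summaries"]["median"].dropna().to_numpy()
        assert (np.diff(med) < 0).all()

    def test_histone_like_class_more_nuclear_than_background(self, default_fit):
        _, _, res = default_fit
        labels = pd.Series(
            np.where(res.table.index.str.contains("histone_like"),
                     "histone_like", "background"),
            index=res.table.index,
        )
        rep = group_compare(res.table, labels)
        tests = rep.sections["group_tests"].set_index("group_a")
        summ = rep.sections["group_summaries"].set_index("group")
        assert summ.loc["histone_like", "median"] > summ.loc["background", "median"]
        assert tests.loc["histone_like", "q"] < 0.05
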