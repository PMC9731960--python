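"""Median split, permutation testing, FDR, correlations, demographics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from plvnet.atlas import NetworkAtlas, ROIEntry
from plvnet.connectivity import PLVMatrixSet
from plvnet.group_stats import (
    GroupSplit,
    StatsError,
    cohens_d,
    correlation_stars,
    demographics_compare,
    fdr_correct,
    median_split,
    mwq_plv_correlations,
    permutation_edge_test,
    run_family_tests,
)


class TestMedianSplit:
    def test_paper_style_split(self):
        scores = {f"s{i}": v for i, v in enumerate([6, 10, 14, 16, 17, 18, 20, 24])}
        split = median_split(scores)
        low = {scores[s] for s in split.low_ids}
        high = {scores[s] for s in split.high_ids}
        assert max(low) < split.median <= min(high)
        assert low == {6, 10, 14, 16} and high == {17, 18, 20, 24}

    def test_no_tie_case(self):
        split = median_split({"a": 1, "b": 2, "c": 3, "d": 4})
        assert sorted(split.low_ids) == ["a", "b"]
        assert sorted(split.high_ids) == ["c", "d"]

    def test_ties_at_median_go_high(self):
        split = median_split({"a": 1, "b": 2, "c": 2, "d": 3})
        assert split.low_ids == ["a"]
        assert sorted(split.high_ids) == ["b", "c", "d"]

    def test_all_equal_rejected(self):
        with pytest.raises(StatsError, match="identical"):
            median_split({"a": 5, "b": 5, "c": 5, "d": 5})

    def test_too_few_subjects_rejected(self):
        with pytest.raises(StatsError, match="at least 4"):
            median_split({"a": 1, "b": 2, "c": 3})


def exhaustive_oracle(lo, hi):
    """Independent enumeration of all distinct splits with scipy's t."""
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    pooled = np.concatenate([lo, hi])
    n_lo = len(lo)
    t_obs = sst.ttest_ind(hi, lo, equal_var=True).statistic
    count = total = 0
    for idx in combinations(range(len(pooled)), n_lo):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        t = sst.ttest_ind(pooled[~mask], pooled[mask], equal_var=True).statistic
        total += 1
        if abs(t) >= abs(t_obs) - 1e-12:
            count += 1
    return t_obs, count / total


class TestPermutationTest:
    def test_identical_constant_groups_p_one(self):
        t, p = permutation_edge_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], n_perm=500)
        assert t == 0.0
        assert p == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        """3-vs-3 groups: full enumeration equals an independent oracle."""
        for _ in range(5):
            lo = rng.normal(size=3)
            hi = rng.normal(loc=0.5, size=3)
            t, p = permutation_edge_test(lo, hi, exact=True)
            t_ref, p_ref = exhaustive_oracle(lo, hi)
            assert t == pytest.approx(t_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_perfect_separation_minimal_p(self):
        """All-0 vs all-1 (n=10 each): only identity-like splits tie."""
        lo, hi = [0.0] * 10, [1.0] * 10
        t, p = permutation_edge_test(lo, hi, n_perm=20000, seed=1)
        assert np.isinf(t) and t > 0
        # true exceedance probability is 2/C(20,10) ~ 1.1e-5
        assert p < 5 / 20001

    def test_monte_carlo_approaches_exact(self, rng):
        lo = rng.normal(size=5)
        hi = rng.normal(loc=1.0, size=5)
        _, p_exact = permutation_edge_test(lo, hi, exact=True)
        _, p_mc = permutation_edge_test(lo, hi, n_perm=20000, seed=2)
        assert abs(p_mc - p_exact) < 0.02

    def test_seed_reproducible(self, rng):
        lo, hi = rng.normal(size=8), rng.normal(size=9)
        r1 = permutation_edge_test(lo, hi, n_perm=1000, seed=5)
        r2 = permutation_edge_test(lo, hi, n_perm=1000, seed=5)
        assert r1 == r2

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_edge_test([0.0, 1.0], [2.0, 3.0], n_perm=50)

    def test_null_p_values_super_uniform(self, rng):
        """Kolmogorov distance of null permutation p-values from U(0,1)."""
        n_edges, n_perm = 400, 400
        ps = np.array([
            permutation_edge_test(
                rng.normal(size=10), rng.normal(size=10), n_perm=n_perm, seed=k
            )[1]
            for k in range(n_edges)
        ])
        grid = np.linspace(0.01, 0.99, 50)
        ecdf = (ps[None, :] <= grid[:, None]).mean(axis=1)
        # super-uniform: ECDF never exceeds the uniform CDF by much
        assert np.max(ecdf - grid) < 0.07


def bh_oracle(p, q):
    """Independent Benjamini-Hochberg step-up (sort-based reference)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    flags = np.zeros(m, bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        flags[order[: k + 1]] = True
    return flags


class TestFdr:
    def test_worked_example_all_flagged(self):
        flags = fdr_correct([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert flags.all()

    def test_large_p_none_flagged(self):
        assert not fdr_correct([0.9, 0.9, 0.9], q=0.05).any()

    def test_single_p_reduces_to_threshold(self):
        assert fdr_correct([0.04], q=0.05)[0]
        assert not fdr_correct([0.06], q=0.05)[0]

    def test_empty_input(self):
        assert fdr_correct([], q=0.05).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsError):
            fdr_correct([0.0, 0.5])

    def test_matches_stepup_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 60))
            assert np.array_equal(fdr_correct(p, 0.05), bh_oracle(p, 0.05))

    def test_flags_monotone(self, rng):
        p = rng.uniform(1e-6, 1, 200)
        flags = fdr_correct(p, 0.05)
        if flags.any() and (~flags).any():
            assert p[flags].max() <= p[~flags].min()


def make_plv_sets(values: np.ndarray, band="alpha", n_rois=4):
    """Build per-subject PLVMatrixSet with edge (0,1) carrying `values`."""
    sets = {}
    rng = np.random.default_rng(99)
    for k, v in enumerate(values):
        m = np.full((n_rois, n_rois), 0.3)
        m[0, 1] = m[1, 0] = v
        m[np.diag_indices(n_rois)] = 1.0
        sets[f"s{k}"] = PLVMatrixSet({band: m}, n_epochs_used=10, subject_id=f"s{k}")
    return sets


@pytest.fixture
def small_atlas():
    return NetworkAtlas(
        [
            ROIEntry("d1", "DMN", "L"),
            ROIEntry("d2", "DMN", "R"),
            ROIEntry("f1", "FPN", "L"),
            ROIEntry("f2", "FPN", "R"),
        ]
    )


class TestFamilyTests:
    def test_planted_effect_flagged_null_not(self, small_atlas, rng):
        n = 30
        vals = np.concatenate([np.full(n, 0.3), np.full(n, 0.7)])
        vals += rng.normal(0, 0.05, 2 * n)
        sets = make_plv_sets(vals)
        split = GroupSplit(0.0, [f"s{k}" for k in range(n)], [f"s{k}" for k in range(n, 2 * n)])
        hyps = [((0, 1), "alpha"), ((2, 3), "alpha")]
        table = run_family_tests(sets, split, hyps, small_atlas, "intra", n_perm=999, seed=3)
        by_edge = {r.edge: r for r in table.results}
        assert by_edge[(0, 1)].p_fdr_significant
        assert not by_edge[(2, 3)].p_fdr_significant
        assert by_edge[(0, 1)].mean_high > by_edge[(0, 1)].mean_low
        assert table.n_significant_fdr <= table.n_significant_raw <= table.n_tests

    def test_single_hypothesis_fdr_equals_raw(self, small_atlas, rng):
        vals = rng.uniform(0.2, 0.8, 20)
        sets = make_plv_sets(vals)
        split = GroupSplit(0.0, [f"s{k}" for k in range(10)], [f"s{k}" for k in range(10, 20)])
        table = run_family_tests(
            sets, split, [((0, 1), "alpha")], small_atlas, "intra", n_perm=999, seed=4
        )
        r = table.results[0]
        assert r.p_fdr_significant == (r.p_perm <= 0.05)

    def test_results_independent_of_hypothesis_order(self, small_atlas, rng):
        vals = rng.uniform(0.2, 0.8, 16)
        sets = make_plv_sets(vals)
        split = GroupSplit(0.0, [f"s{k}" for k in range(8)], [f"s{k}" for k in range(8, 16)])
        hyps = [((0, 1), "alpha"), ((2, 3), "alpha")]
        t1 = run_family_tests(sets, split, hyps, small_atlas, "intra", n_perm=500, seed=6)
        t2 = run_family_tests(sets, split, hyps[::-1], small_atlas, "intra", n_perm=500, seed=6)
        a = {r.edge: r.p_perm for r in t1.results}
        b = {r.edge: r.p_perm for r in t2.results}
        assert a == b

    def test_missing_subject_named(self, small_atlas):
        sets = make_plv_sets(np.full(4, 0.5))
        split = GroupSplit(0.0, ["s0", "s1"], ["s2", "missing"])
        with pytest.raises(StatsError, match="missing"):
            run_family_tests(sets, split, [((0, 1), "alpha")], small_atlas, "intra", 100, 0)


class TestCorrelations:
    def test_affine_map_gives_unit_r(self):
        scores = {f"s{k}": float(k) for k in range(10)}
        sets = make_plv_sets(0.05 * np.arange(10) + 0.1)
        (r, p), = mwq_plv_correlations(sets, scores, [((0, 1), "alpha")])
        assert r == pytest.approx(1.0)

    def test_exact_antilinear(self):
        scores = {"s0": 1.0, "s1": 2.0, "s2": 3.0}
        sets = make_plv_sets(np.array([0.6, 0.4, 0.2]))
        (r, _), = mwq_plv_correlations(sets, scores, [((0, 1), "alpha")])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self):
        scores = {f"s{k}": float(k) for k in range(5)}
        sets = make_plv_sets(np.full(5, 0.5))
        (r, p), = mwq_plv_correlations(sets, scores, [((0, 1), "alpha")])
        assert r is None and p is None

    def test_star_thresholds(self):
        assert correlation_stars(0.0005) == "***"
        assert correlation_stars(0.005) == "**"
        assert correlation_stars(0.03) == "*"
        assert correlation_stars(0.2) == ""
        assert correlation_stars(None) == "n/a"


def exact_moments(z, mean, sd):
    """Rescale a vector to exact sample mean/SD (ddof=1)."""
    z = (z - z.mean()) / z.std(ddof=1)
    return z * sd + mean


class TestDemographics:
    def metadata(self, hi_vals, lo_vals, hi_sex=None, lo_sex=None):
        n_hi, n_lo = len(hi_vals), len(lo_vals)
        rows = []
        for k in range(n_hi):
            rows.append(("h%d" % k, hi_vals[k], 20.0, (hi_sex or "M" * n_hi)[k], 15.0, 90.0))
        for k in range(n_lo):
            rows.append(("l%d" % k, lo_vals[k], 20.0, (lo_sex or "M" * n_lo)[k], 15.0, 90.0))
        return pd.DataFrame(
            rows, columns=["subject", "mwq_total", "age", "sex", "education", "spm_pr"]
        )


    def split_for(self, meta):
        hi = [s for s in meta["subject"] if s.startswith("h")]
        lo = [s for s in meta["subject"] if s.startswith("l")]
        return GroupSplit(0.0, lo, hi)

    def test_identical_groups_null(self, rng):
        vals = rng.normal(18, 2, 10)
        meta = self.metadata(vals, vals)
        out = demographics_compare(meta, self.split_for(meta))
        row = out[out["variable"] == "mwq_total"].iloc[0]
        assert row["effect"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] > 0.99

    def test_effect_size_matches_published_magnitude(self, rng):
        """Means 18.87/12.82, SDs 1.92/2.59, n 34/32: pooled d ~ 2.67."""
        hi = exact_moments(rng.normal(size=34), 18.87, 1.92)
        lo = exact_moments(rng.normal(size=32), 12.82, 2.59)
        meta = self.metadata(hi, lo)
        out = demographics_compare(meta, self.split_for(meta))
        row = out[out["variable"] == "mwq_total"].iloc[0]
        assert row["effect"] == pytest.approx(2.666, abs=0.01)
        assert row["stat"] == pytest.approx(10.83, abs=0.1)
        assert row["p"] < 1e-4

    def test_balanced_sex_chi2_zero(self, rng):
        meta = self.metadata(
            rng.normal(18, 2, 10), rng.normal(13, 2, 10),
            hi_sex="MMMMMFFFFF", lo_sex="MMMMMFFFFF",
        )
        out = demographics_compare(meta, self.split_for(meta))
        row = out[out["variable"] == "sex_pct_male"].iloc[0]
        assert row["stat"] == pytest.approx(0.0, abs=1e-12)
        assert row["effect"] == pytest.approx(0.0, abs=1e-12)

    def test_cohens_d_pooled_formula(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        sp = np.sqrt((19 * x.var(ddof=1) + 24 * y.var(ddof=1)) / 43)
        assert cohens_d(x, y) == pytest.approx(abs(x.mean() - y.mean()) / sp)

    def test_small_group_rejected(self, rng):
        meta = self.metadata(rng.normal(size=1), rng.normal(size=5))
        with pytest.raises(StatsError):
            demographics_compare(meta, self.split_for(meta))
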