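from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glomquant import tables
from glomquant.stats import (
    bootstrap_ci_median,
    group_summary,
    iqr,
    mann_whitney_exact,
    quantiles_linear,
)


def brute_force_mw(a, b):
    """Independent oracle: U by direct pair counting and exact doubled-tail
    p by enumerating every split of the pooled values."""
    a, b = list(a), list(b)

    def u_of(x, y):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0)
            for xi in x for yi in y
        )

    u_obs = u_of(a, b)
    pooled = a + b
    n1 = len(a)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        first = [pooled[i] for i in idx]
        second = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_of(first, second))
    us = np.array(us)
    le = np.mean(us <= u_obs + 1e-9)
    ge = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2 * min(le, ge))


class TestQuantilesLinear:
    def test_published_quartile_values(self):
        q1, med, q3 = quantiles_linear([2473, 2560, 2788, 2792])
        assert (q1, med, q3) == (2538.25, 2674.0, 2789.0)
        q1, med, q3 = quantiles_linear([2828, 2845, 2857, 2931])
        assert med == 2851.0
        assert q3 - q1 == pytest.approx(34.75)

    def test_singleton_and_empty(self):
        assert quantiles_linear([5.0]) == (5.0, 5.0, 5.0)
        with pytest.raises(ValueError):
            quantiles_linear([])

    def test_closed_form_positions_on_integer_ranges(self):
        # oracle loop: for {0..n}, the p-quantile sits exactly at p*n
        for n in range(1, 21):
            x = np.arange(n + 1, dtype=float)
            q1, med, q3 = quantiles_linear(x)
            assert q1 == pytest.approx(0.25 * n)
            assert med == pytest.approx(0.5 * n)
            assert q3 == pytest.approx(0.75 * n)


class TestGroupSummary:
    def test_published_group_medians(self):
        t2 = tables.load_counts_sizes()
        diam = tables.group_values(t2, "median_effective_diameter_um")
        s = group_summary(diam["PD56"], seed=0)
        from glomquant.stats import round_half_up

        assert s["median"] == pytest.approx(77.535)
        assert round_half_up(s["median"], 2) == 77.54
        counts = tables.group_values(t2, "n_glomeruli")
        assert group_summary(counts["PD21"], seed=0)["median"] == 2674.0

    def test_identical_medians_and_validation(self):
        s = group_summary([4.2, 4.2, 4.2, 4.2], seed=1)
        assert s["median"] == 4.2 and s["iqr"] == 0.0
        with pytest.raises(ValueError):
            group_summary([1.0])


class TestMannWhitneyExact:
    def test_null_pmf_at_four_vs_four(self):
        # tie-free null: U counts over 0..16 from enumerating 70 splits
        a, b = [1, 2, 3, 4], [5, 6, 7, 8]
        pooled = a + b
        counts = np.zeros(17)
        for idx in combinations(range(8), 4):
            first = [pooled[i] for i in idx]
            second = [pooled[i] for i in range(8) if i not in idx]
            u = sum(1 for x in first for y in second if x > y)
            counts[u] += 1
        expected = [1, 1, 2, 3, 5, 5, 7, 7, 8, 7, 7, 5, 5, 3, 2, 1, 1]
        assert counts.tolist() == expected

    @pytest.mark.parametrize("u_target,p_expected", [
        (0, 2 / 70), (4, 24 / 70), (6, 48 / 70), (8, 1.0), (11, 34 / 70),
    ])
    def test_doubled_tail_p_on_tie_free_null(self, u_target, p_expected):
        # realize each U with a concrete tie-free 4-vs-4 sample
        arrangements = {
            0: ([1, 2, 3, 4], [5, 6, 7, 8]),
            4: ([1, 2, 5, 6], [3, 4, 7, 8]),
            6: ([1, 4, 5, 6], [2, 3, 7, 8]),
            8: ([1, 4, 5, 8], [2, 3, 6, 7]),
            11: ([2, 5, 6, 8], [1, 3, 4, 7]),
        }
        a, b = arrangements[u_target]
        res = mann_whitney_exact(a, b)
        assert res.u_stat == u_target
        assert res.p_exact_two_sided == pytest.approx(p_expected)

    def test_published_group_comparisons(self):
        t2 = tables.load_counts_sizes()
        counts = tables.group_values(t2, "n_glomeruli")
        r = mann_whitney_exact(counts["PD14"], counts["PD56"])
        assert r.u_stat == 0 and r.p_exact_two_sided == pytest.approx(2 / 70)
        r = mann_whitney_exact(counts["PD14"], counts["PD21"])
        assert r.u_stat == 12 and r.p_exact_two_sided == pytest.approx(24 / 70)

    def test_agrees_with_brute_force_with_and_without_ties(self):
        rng = np.random.default_rng(17)
        for trial in range(8):
            a = rng.integers(0, 6, size=rng.integers(2, 6)).astype(float)
            b = rng.integers(0, 6, size=rng.integers(2, 6)).astype(float)
            res = mann_whitney_exact(a, b)
            u_bf, p_bf = brute_force_mw(a, b)
            assert res.u_stat == pytest.approx(u_bf)
            assert res.p_exact_two_sided == pytest.approx(p_bf)

    def test_agrees_with_scipy_when_tie_free(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 5)
        from scipy.stats import mannwhitneyu

        res = mann_whitney_exact(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.u_stat == pytest.approx(ref.statistic)
        assert res.p_exact_two_sided == pytest.approx(ref.pvalue)

    def test_identical_singleton_samples(self):
        res = mann_whitney_exact([3.0, 3.0], [3.0, 3.0])
        assert res.u_stat == pytest.approx(2.0)  # all four pairs tie at 0.5
        assert res.p_exact_two_sided == 1.0

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.8, 1, 60)
        res = mann_whitney_exact(a, b)
        assert not res.exact
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        # scipy applies a continuity correction; agreement is approximate
        assert res.p_exact_two_sided == pytest.approx(ref.pvalue, rel=0.1, abs=1e-4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 9), min_size=1, max_size=5),
        b=st.lists(st.integers(0, 9), min_size=1, max_size=5),
    )
    def test_antisymmetry_property(self, a, b):
        u_ab = mann_whitney_exact(a, b).u_stat
        u_ba = mann_whitney_exact(b, a).u_stat
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestBootstrapCI:
    def test_constant_sample_collapses(self):
        assert bootstrap_ci_median([7.0] * 5, seed=0) == (7.0, 7.0)

    def test_interval_within_sample_support_and_deterministic(self):
        x = [210_177.0, 167_843.0, 129_866.0, 146_564.0]
        lo, hi = bootstrap_ci_median(x, seed=99)
        assert min(x) <= lo <= hi <= max(x)
        assert bootstrap_ci_median(x, seed=99) == (lo, hi)

    def test_small_sample_interval_spans_min_max(self):
        # at n=4 the percentile interval reaches the published bracket
        # endpoints, which are the sample extremes
        x = [210_177.0, 167_843.0, 129_866.0, 146_564.0]
        lo, hi = bootstrap_ci_median(x, n_boot=20_000, seed=1)
        assert lo == pytest.approx(129_866.0, rel=0.05)
        assert hi == pytest.approx(210_177.0, rel=0.05)

    def test_nominal_coverage_on_normal_samples(self):
        rng = np.random.default_rng(31)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            x = rng.normal(0, 1, 50)
            lo, hi = bootstrap_ci_median(x, n_boot=500, seed=1000 + i)
            hits += lo <= 0 <= hi
        assert 0.88 <= hits / n_rep <= 0.99

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci_median([1.0])


def test_iqr_reproduces_table_note_values():
    t2 = tables.load_counts_sizes()
    counts = tables.group_values(t2, "n_glomeruli")
    assert iqr(counts["PD14"]) == pytest.approx(46.75)
    assert iqr(counts["PD21"]) == pytest.approx(250.75)
    assert iqr(counts["PD56"]) == pytest.approx(34.75)
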