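import itertools

import numpy as np
import pytest
from scipy import stats

from soasim.constants import ACTION_LATENCIES_MS, ACTION_LINKED, EPA, EPA_OFFSETS_MS
from soasim.errors import EvaluationError
from soasim.evaluation import (
    RateDistribution,
    YesRateCurve,
    classify_m_subject,
    curve_rmse,
    group_curves,
    kl_distributions,
    mann_whitney_u,
    mse_distributions,
    rate_distribution,
    unit_significance_counts,
    window_summary,
    yes_rate_curve,
)


def make_curve(action_value=0.5, epa_value=0.5, overrides=None):
    action = {ms: action_value for ms in ACTION_LATENCIES_MS}
    action.update(overrides or {})
    return YesRateCurve(action, {ms: epa_value for ms in EPA_OFFSETS_MS})


def brute_force_u(x, y):
    """U statistic by exhaustive pair enumeration (greater + half ties)."""
    return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi, yi in itertools.product(x, y))


class TestYesRateCurve:
    def test_counting_rule(self):
        final = np.concatenate([np.full(90, 0.9), np.full(10, 0.1)])
        tts, conds = [], []
        for ms in ACTION_LATENCIES_MS:
            tts += [ACTION_LINKED] * 7
            conds += [ms] * 7
        for ms in EPA_OFFSETS_MS:
            tts += [EPA] * 7
            conds += [ms] * 7
        vals = np.resize([0.9, 0.9, 0.9, 0.1, 0.9, 0.9, 0.9], 98)
        curve = yes_rate_curve(vals, tts, np.array(conds))
        for ms in ACTION_LATENCIES_MS:
            assert curve.action_rates[ms] == pytest.approx(6 / 7)

    def test_exact_half_counts_as_no(self):
        tts = [ACTION_LINKED] * 11 + [EPA] * 3
        conds = list(ACTION_LATENCIES_MS) + list(EPA_OFFSETS_MS)
        curve = yes_rate_curve(np.full(14, 0.5), tts, np.array(conds))
        assert all(r == 0.0 for r in curve.action_rates.values())

    def test_missing_condition_raises(self):
        with pytest.raises(EvaluationError, match=r"no trials for condition \(action_linked, 100\)"):
            yes_rate_curve(np.array([0.9]), [ACTION_LINKED], np.array([0]))


class TestWindowSummary:
    def test_short_window_of_ones(self):
        c = make_curve(0.0, 0.0, {0: 1.0, 100: 1.0, 200: 1.0})
        assert window_summary(c).short_avg == 1.0

    def test_arithmetic_mean(self):
        c = make_curve(0.0, 0.0, {0: 0.9, 100: 0.8, 200: 0.7})
        assert window_summary(c).short_avg == pytest.approx(0.8)

    def test_constant_curve(self):
        s = window_summary(make_curve(0.3, 0.3))
        assert s.short_avg == pytest.approx(0.3) and s.long_avg == pytest.approx(0.3)


class TestRateDistribution:
    def test_all_ones_in_last_bin(self):
        d = rate_distribution([1.0] * 5)
        assert d.probabilities[-1] == 1.0

    def test_extremes_split(self):
        d = rate_distribution([0.0, 1.0])
        assert d.probabilities[0] == 0.5 and d.probabilities[-1] == 0.5

    def test_edge_value_goes_to_upper_bin(self):
        edges = np.linspace(0, 1, 12)
        d = rate_distribution([float(edges[3])])
        assert d.probabilities[3] == 1.0

    def test_uniform_draws_near_uniform(self):
        rng = np.random.default_rng(0)
        d = rate_distribution(rng.uniform(0, 1, 1000))
        se = np.sqrt((1 / 11) * (10 / 11) / 1000)
        assert np.all(np.abs(d.probabilities - 1 / 11) < 3 * se)

    def test_out_of_range_rejected(self):
        with pytest.raises(EvaluationError):
            rate_distribution([1.2])


class TestDistances:
    def test_identical_distributions_zero(self):
        d = rate_distribution([0.1, 0.5, 0.9])
        assert mse_distributions(d, d) == 0.0
        assert kl_distributions(d, d) == pytest.approx(0.0, abs=1e-12)

    def test_mse_disjoint_two_bins(self):
        e = np.array([0.0, 0.5, 1.0])
        p = RateDistribution(e, np.array([1.0, 0.0]))
        q = RateDistribution(e, np.array([0.0, 1.0]))
        assert mse_distributions(p, q) == pytest.approx(1.0)
        assert mse_distributions(p, q) == mse_distributions(q, p)

    def test_kl_closed_form(self):
        e = np.array([0.0, 0.5, 1.0])
        p = RateDistribution(e, np.array([0.5, 0.5]))
        q = RateDistribution(e, np.array([0.9, 0.1]))
        eps = 1e-6
        ps = (np.array([0.5, 0.5]) + eps) / (1 + 2 * eps)
        qs = (np.array([0.9, 0.1]) + eps) / (1 + 2 * eps)
        expected = np.sum(ps * np.log(ps / qs))
        assert kl_distributions(p, q) == pytest.approx(expected, rel=1e-12)

    def test_kl_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rate_distribution(rng.uniform(0, 1, 30))
            q = rate_distribution(rng.uniform(0, 1, 30))
            assert kl_distributions(p, q) >= 0.0

    def test_mismatched_bins_rejected(self):
        p = rate_distribution([0.5], n_bins=11)
        q = rate_distribution([0.5], n_bins=5)
        with pytest.raises(EvaluationError):
            mse_distributions(p, q)


class TestClassification:
    def test_identical_curves_no_change(self):
        c = make_curve(0.7, 0.2)
        res = classify_m_subject(c, c, "m")
        assert res.y_short == 0.0 and res.y_long == 0.0 and res.label == "no_change"

    def test_halved_short_rates_diminished(self):
        healthy = make_curve(0.0, 0.0, {0: 1.0, 100: 1.0, 200: 1.0})
        lesioned = make_curve(0.0, 0.0, {0: 0.5, 100: 0.5, 200: 0.5})
        res = classify_m_subject(lesioned, healthy, "m")
        assert res.y_short == pytest.approx(-5.0)
        assert res.label == "diminished"

    def test_raised_long_rates_excessive(self):
        healthy = make_curve(1.0, 0.0, {800: 0.0, 900: 0.0, 1000: 0.0})
        lesioned = make_curve(1.0, 0.0, {800: 0.6, 900: 0.6, 1000: 0.6})
        res = classify_m_subject(lesioned, healthy, "m")
        assert res.y_long == pytest.approx(6.0)
        assert res.label == "excessive"

    def test_both_directions_sz_pattern(self):
        healthy = make_curve(0.5, 0.0, {0: 1.0, 100: 1.0, 200: 1.0, 800: 0.0, 900: 0.0, 1000: 0.0})
        lesioned = make_curve(0.5, 0.0, {0: 0.5, 100: 0.5, 200: 0.5, 800: 0.5, 900: 0.5, 1000: 0.5})
        assert classify_m_subject(lesioned, healthy, "m").label == "sz_pattern"

    def test_scale_consistency(self):
        healthy = make_curve(0.4, 0.1, {800: 0.1})
        lesioned = make_curve(0.6, 0.1, {800: 0.55})
        a = classify_m_subject(lesioned, healthy, "m", thresholds=(-2, 2), rate_scale=10)
        b = classify_m_subject(lesioned, healthy, "m", thresholds=(-4, 4), rate_scale=20)
        assert a.label == b.label


class TestGroupCurves:
    def test_single_member_has_zero_se(self):
        res = classify_m_subject(make_curve(0.5), make_curve(0.5), "m")
        out = group_curves([(res, make_curve(0.5))])
        assert np.all(out["no_change"]["se"] == 0.0)

    def test_mean_and_se_match_direct_arithmetic(self):
        curves = [make_curve(v) for v in (0.2, 0.4, 0.9)]
        results = [classify_m_subject(c, c, f"m{i}") for i, c in enumerate(curves)]
        out = group_curves(list(zip(results, curves)))["no_change"]
        stacked = np.stack([c.as_array() for c in curves])
        assert np.allclose(out["mean"], stacked.mean(axis=0))
        assert np.allclose(out["se"], stacked.std(axis=0, ddof=1) / np.sqrt(3))


class TestRankStatistics:
    def test_u_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.integers(0, 10, rng.integers(2, 8)).astype(float)
            y = rng.integers(0, 10, rng.integers(2, 8)).astype(float)
            u, _ = mann_whitney_u(x, y)
            assert u == pytest.approx(brute_force_u(x, y))

    def test_fully_separated_lists(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_lists_p_one(self):
        u, p = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0])
        assert u == 3.0 and p == 1.0

    def test_spearman_brute_force_small_lists(self):
        # rank correlation from first principles on lists of length <= 8
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert stats.spearmanr(x, y).statistic == pytest.approx(expected, rel=1e-10)


class TestUnitSignificance:
    def test_constant_unit_never_significant(self):
        rng = np.random.default_rng(3)
        n = 200
        act = np.column_stack([np.full(n, 0.7), rng.uniform(size=n)])
        judgments = rng.random(n) < 0.5
        latencies = rng.choice(ACTION_LATENCIES_MS, n)
        n_soa, n_lat = unit_significance_counts(act, judgments, latencies)
        # the constant first unit contributes to neither count
        assert n_soa <= 1 and n_lat <= 1

    def test_perfect_latency_coding_significant(self):
        latencies = np.repeat(ACTION_LATENCIES_MS, 10).astype(float)
        act = (latencies / 1000.0)[:, None]
        judgments = latencies < 500
        n_soa, n_lat = unit_significance_counts(act, judgments, latencies)
        assert n_lat == 1 and n_soa == 1

    def test_single_class_judgments_skipped(self):
        act = np.random.default_rng(0).uniform(size=(50, 2))
        lat = np.resize(ACTION_LATENCIES_MS, 50).astype(float)
        n_soa, n_lat = unit_significance_counts(act, np.ones(50, dtype=bool), lat)
        assert n_soa is None


def test_curve_rmse_uniform_offset():
    a = make_curve(0.5, 0.5)
    b = make_curve(0.6, 0.6)
    assert curve_rmse(a, b) == pytest.approx(0.1)
    assert curve_rmse(a, a) == 0.0
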