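"""Summary statistics for agency-judgment experiments.

Covers per-condition yes-rate curves, short/long latency-window
averages, normalized histograms of window averages with MSE and
KL-divergence distances, classification of lesioned model subjects into
excessive / diminished / schizophrenia-pattern groups, and the
context-unit functional correlation analysis (Mann-Whitney U against
the yes/no judgment, Spearman rank correlation against the latency
condition).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import (
    ACTION_LATENCIES_MS,
    ACTION_LINKED,
    EPA,
    EPA_OFFSETS_MS,
    LONG_WINDOW_MS,
    SHORT_WINDOW_MS,
)
from .errors import EvaluationError

#: Model output is read as "yes" iff the final agency-channel value
#: exceeds this midpoint of the 0.1/0.9 target coding.
YES_THRESHOLD = 0.5


@dataclass(frozen=True)
class YesRateCurve:
    """Yes rate for each of the 11 action-linked + 3 EPA conditions."""

    action_rates: dict[int, float]
    epa_rates: dict[int, float]
    n_per_condition: dict[tuple[str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [ms for ms in ACTION_LATENCIES_MS if ms not in self.action_rates]
        missing += [ms for ms in EPA_OFFSETS_MS if ms not in self.epa_rates]
        if missing:
            raise EvaluationError(f"curve is missing conditions: {missing}")
        for r in list(self.action_rates.values()) + list(self.epa_rates.values()):
            if not 0.0 <= r <= 1.0:
                raise EvaluationError(f"yes rate out of [0,1]: {r}")

    def as_array(self) -> np.ndarray:
        """Rates in canonical order: 11 latencies then 3 EPA offsets."""
        return np.array(
            [self.action_rates[ms] for ms in ACTION_LATENCIES_MS]
            + [self.epa_rates[ms] for ms in EPA_OFFSETS_MS]
        )


@dataclass(frozen=True)
class WindowSummary:
    short_avg: float  # mean yes rate over 0/100/200 ms
    long_avg: float  # mean yes rate over 800/900/1000 ms


@dataclass(frozen=True)
class RateDistribution:
    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise EvaluationError("probabilities must be non-negative and sum to 1")


@dataclass(frozen=True)
class ClassificationResult:
    m_subject_id: str
    y_short: float
    y_long: float
    label: str  # excessive | diminished | sz_pattern | no_change


@dataclass(frozen=True)
class UnitCorrelationReport:
    """Counts of functionally involved context units, per model subject."""

    soa_counts: dict[str, int]  # significant vs yes/no judgment (MWU, p<.05)
    latency_counts: dict[str, int]  # significant vs latency (Spearman, p<.01)
    mean_soa_units: float
    mean_latency_units: float
    skipped: tuple[str, ...] = ()  # subjects with single-class judgments


def yes_rate_curve(
    final_soa: np.ndarray,
    trial_types: list[str],
    conditions_ms: np.ndarray,
    threshold: float = YES_THRESHOLD,
) -> YesRateCurve:
    """Per-condition rate of final agency outputs strictly above threshold."""
    final_soa = np.asarray(final_soa, dtype=float)
    conditions_ms = np.asarray(conditions_ms)
    trial_types = np.asarray(trial_types)
    action_rates, epa_rates, n_per = {}, {}, {}
    for tt, grid, out in (
        (ACTION_LINKED, ACTION_LATENCIES_MS, action_rates),
        (EPA, EPA_OFFSETS_MS, epa_rates),
    ):
        for ms in grid:
            sel = (trial_types == tt) & (conditions_ms == ms)
            n = int(sel.sum())
            if n == 0:
                raise EvaluationError(f"no trials for condition ({tt}, {ms})")
            out[ms] = float(np.mean(final_soa[sel] > threshold))
            n_per[(tt, ms)] = n
    return YesRateCurve(action_rates, epa_rates, n_per)


def window_summary(curve: YesRateCurve) -> WindowSummary:
    return WindowSummary(
        short_avg=float(np.mean([curve.action_rates[ms] for ms in SHORT_WINDOW_MS])),
        long_avg=float(np.mean([curve.action_rates[ms] for ms in LONG_WINDOW_MS])),
    )


def rate_distribution(values, n_bins: int = 11) -> RateDistribution:
    """Normalized histogram of window-averaged yes rates on [0, 1].

    A value on an interior bin edge belongs to the upper bin; 1.0 goes
    to the last bin.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise EvaluationError("need at least one value")
    if np.any((values < 0) | (values > 1)):
        raise EvaluationError("window averages must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(values, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return RateDistribution(bin_edges=edges, probabilities=counts / counts.sum())


def _check_bins(p: RateDistribution, q: RateDistribution) -> None:
    if p.bin_edges.shape != q.bin_edges.shape or not np.allclose(p.bin_edges, q.bin_edges):
        raise EvaluationError("distributions have mismatched bin edges")


def mse_distributions(p: RateDistribution, q: RateDistribution) -> float:
    """Mean over bins of the squared probability difference."""
    _check_bins(p, q)
    return float(np.mean((p.probabilities - q.probabilities) ** 2))


def kl_distributions(p: RateDistribution, q: RateDistribution, eps: float = 1e-6) -> float:
    """KL(P||Q) after additive-eps smoothing and renormalization.

    P is the data/reference distribution and Q the model/lesion
    distribution; smoothing keeps empty bins finite.
    """
    _check_bins(p, q)
    ps = p.probabilities + eps
    qs = q.probabilities + eps
    ps /= ps.sum()
    qs /= qs.sum()
    return float(np.sum(ps * np.log(ps / qs)))


def distribution_distance(
    ref_short: RateDistribution,
    ref_long: RateDistribution,
    model_short: RateDistribution,
    model_long: RateDistribution,
) -> dict[str, float]:
    """One MSE and one KL per comparison: short/long windows averaged."""
    return {
        "mse": 0.5 * (mse_distributions(ref_short, model_short) + mse_distributions(ref_long, model_long)),
        "kl": 0.5 * (kl_distributions(ref_short, model_short) + kl_distributions(ref_long, model_long)),
    }


def classify_m_subject(
    lesioned: YesRateCurve,
    healthy: YesRateCurve,
    m_subject_id: str = "",
    thresholds: tuple[float, float] = (-2.0, 2.0),
    rate_scale: float = 10.0,
) -> ClassificationResult:
    """Window scores Y = sum_j scale*(lesioned_j - healthy_j) / 3.

    Rates are put on a 0-10 count-equivalent scale (10 repetitions per
    condition) so the -2/+2 thresholds correspond to a 0.2 mean rate
    change. Excessive: Y_long above the upper threshold; diminished:
    Y_short below the lower threshold; schizophrenia-pattern: both.
    """
    lower, upper = thresholds
    y = lambda window: float(  # noqa: E731
        sum(
            rate_scale * (lesioned.action_rates[ms] - healthy.action_rates[ms])
            for ms in window
        )
        / len(window)
    )
    y_short, y_long = y(SHORT_WINDOW_MS), y(LONG_WINDOW_MS)
    exc, dim = y_long > upper, y_short < lower
    label = "sz_pattern" if (exc and dim) else "excessive" if exc else "diminished" if dim else "no_change"
    return ClassificationResult(m_subject_id, y_short, y_long, label)


def group_curves(
    results: list[tuple[ClassificationResult, YesRateCurve]]
) -> dict[str, dict[str, np.ndarray]]:
    """Condition-wise mean and standard error of curves per label group."""
    groups: dict[str, list[np.ndarray]] = {}
    for res, curve in results:
        groups.setdefault(res.label, []).append(curve.as_array())
    out = {}
    for label, arrays in groups.items():
        a = np.stack(arrays)
        n = a.shape[0]
        se = a.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(a.shape[1])
        out[label] = {"mean": a.mean(axis=0), "se": se, "n": n}
    return out


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected).

    Degenerate all-tied samples report U = n*m/2 with p = 1 instead of
    raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EvaluationError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return x.size * y.size / 2.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def unit_significance_counts(
    prejump_activations: np.ndarray,
    judgments: np.ndarray,
    latencies_ms: np.ndarray,
    alpha_soa: float = 0.05,
    alpha_latency: float = 0.01,
) -> tuple[int | None, int]:
    """Significant-unit counts for one model subject.

    ``prejump_activations``: (n_trials, n_units) context activations at
    the step immediately before the piece jump, over action-linked test
    trials. The judgment count is None when every trial got the same
    judgment (the between-groups test is undefined).
    """
    act = np.asarray(prejump_activations, dtype=float)
    judgments = np.asarray(judgments, dtype=bool)
    latencies_ms = np.asarray(latencies_ms, dtype=float)
    n_units = act.shape[1]
    n_soa: int | None
    if judgments.all() or (~judgments).all():
        n_soa = None
    else:
        n_soa = 0
        for k in range(n_units):
            _, p = mann_whitney_u(act[judgments, k], act[~judgments, k])
            if p < alpha_soa:
                n_soa += 1
    n_lat = 0
    for k in range(n_units):
        if np.ptp(act[:, k]) == 0.0:
            continue  # constant unit: no association by definition
        rho, p = stats.spearmanr(act[:, k], latencies_ms)
        if np.isfinite(p) and p < alpha_latency:
            n_lat += 1
    return n_soa, n_lat


def unit_correlation_report(
    per_subject: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    alpha_soa: float = 0.05,
    alpha_latency: float = 0.01,
) -> UnitCorrelationReport:
    """Cohort aggregation of :func:`unit_significance_counts`.

    ``per_subject`` maps m_subject_id to (prejump_activations,
    judgments, latencies_ms).
    """
    soa_counts: dict[str, int] = {}
    lat_counts: dict[str, int] = {}
    skipped = []
    for sid, (act, judg, lat) in per_subject.items():
        n_soa, n_lat = unit_significance_counts(act, judg, lat, alpha_soa, alpha_latency)
        lat_counts[sid] = n_lat
        if n_soa is None:
            skipped.append(sid)
        else:
            soa_counts[sid] = n_soa
    if not lat_counts:
        raise EvaluationError("no subjects to aggregate")
    return UnitCorrelationReport(
        soa_counts=soa_counts,
        latency_counts=lat_counts,
        mean_soa_units=float(np.mean(list(soa_counts.values()))) if soa_counts else float("nan"),
        mean_latency_units=float(np.mean(list(lat_counts.values()))),
        skipped=tuple(skipped),
    )


def curve_rmse(a: YesRateCurve, b: YesRateCurve) -> float:
    """Root mean square difference over the 14-condition grid."""
    return float(np.sqrt(np.mean((a.as_array() - b.as_array()) ** 2)))
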