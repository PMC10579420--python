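"""Synthetic behavioral data for the agency-attribution task.

No behavioral recordings ship with this package; instead each synthetic
"H-subject" is a draw from a cohort-level distribution of psychometric
profiles. A subject's probability of reporting agency ("yes") on an
action-linked trial follows a four-parameter logistic in the jumping
latency L (ms),

    p(L) = lower + (upper - lower) * sigma(-slope * (L - inflection)),

which is monotone decreasing in L for slope > 0 and has its half-way
point at the inflection latency. EPA (beep-locked jump) trials get a
constant per-condition yes-probability. Button-press reaction times are
normal, truncated to be strictly positive.

Schizophrenia-pattern reference curves (paranoid-type PS: elevated yes
rates at long latencies and on EPA trials; negative-symptom NS: reduced
yes rates at short latencies) are synthetic stand-ins generated from
shifted parameter ranges — they are configuration, not patient data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .constants import (
    ACTION_LATENCIES_MS,
    ACTION_LINKED,
    EPA,
    EPA_OFFSETS_MS,
    N_REPEATS_PER_CONDITION,
    N_TRIALS_PER_SUBJECT,
)
from .errors import ConfigurationError
from .evaluation import YesRateCurve

SeedLike = "int | np.random.SeedSequence"


def subject_seed(master_seed: int, subject_index: int, stream: int) -> np.random.SeedSequence:
    """Counter-scheme seed derivation: stream 0 = profile, 1 = trials.

    Any subject of a cohort is regenerable in isolation from
    ``(master_seed, subject_index)``.
    """
    return np.random.SeedSequence([int(master_seed), int(subject_index), int(stream)])


@dataclass(frozen=True)
class SubjectProfile:
    """Generative psychometric parameters of one synthetic subject."""

    subject_id: str
    inflection_ms: float
    slope: float  # per ms
    upper_asymptote: float
    lower_asymptote: float
    epa_yes_prob: tuple[float, float, float]  # keyed by EPA_OFFSETS_MS order
    rt_mean_ms: float
    rt_sd_ms: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_asymptote < self.upper_asymptote <= 1.0):
            raise ConfigurationError(
                "asymptotes must satisfy 0 <= lower < upper <= 1, got "
                f"lower={self.lower_asymptote}, upper={self.upper_asymptote}"
            )
        if not (0.0 <= self.inflection_ms <= 1000.0):
            raise ConfigurationError(f"inflection_ms out of [0, 1000]: {self.inflection_ms}")
        if self.slope <= 0:
            raise ConfigurationError(f"slope must be > 0: {self.slope}")
        if self.rt_mean_ms <= 0 or self.rt_sd_ms < 0:
            raise ConfigurationError("rt_mean_ms must be > 0 and rt_sd_ms >= 0")
        if len(self.epa_yes_prob) != len(EPA_OFFSETS_MS):
            raise ConfigurationError("epa_yes_prob needs one value per EPA offset")
        for p in self.epa_yes_prob:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"EPA yes-probability out of [0,1]: {p}")


@dataclass(frozen=True)
class Trial:
    trial_type: str  # ACTION_LINKED or EPA
    condition_ms: int  # latency (action-linked) or beep-relative offset (EPA)
    rt_ms: float
    response: int  # 1 = yes, 0 = no

    def __post_init__(self) -> None:
        if self.trial_type == ACTION_LINKED:
            if self.condition_ms not in ACTION_LATENCIES_MS:
                raise ConfigurationError(f"invalid latency: {self.condition_ms}")
        elif self.trial_type == EPA:
            if self.condition_ms not in EPA_OFFSETS_MS:
                raise ConfigurationError(f"invalid EPA offset: {self.condition_ms}")
        else:
            raise ConfigurationError(f"unknown trial type: {self.trial_type!r}")
        if self.rt_ms <= 0:
            raise ConfigurationError(f"rt_ms must be > 0: {self.rt_ms}")
        if self.response not in (0, 1):
            raise ConfigurationError(f"response must be 0/1: {self.response}")


@dataclass(frozen=True)
class BehavioralDataset:
    subject_id: str
    trials: tuple[Trial, ...]
    profile: SubjectProfile

    def __post_init__(self) -> None:
        if len(self.trials) != N_TRIALS_PER_SUBJECT:
            raise ConfigurationError(
                f"expected {N_TRIALS_PER_SUBJECT} trials, got {len(self.trials)}"
            )

    def empirical_curve(self) -> YesRateCurve:
        """Per-condition yes rates actually recorded in this dataset."""
        action: dict[int, list[int]] = {ms: [] for ms in ACTION_LATENCIES_MS}
        epa: dict[int, list[int]] = {ms: [] for ms in EPA_OFFSETS_MS}
        for tr in self.trials:
            (action if tr.trial_type == ACTION_LINKED else epa)[tr.condition_ms].append(
                tr.response
            )
        return YesRateCurve(
            action_rates={ms: float(np.mean(v)) for ms, v in action.items()},
            epa_rates={ms: float(np.mean(v)) for ms, v in epa.items()},
            n_per_condition={
                **{(ACTION_LINKED, ms): len(v) for ms, v in action.items()},
                **{(EPA, ms): len(v) for ms, v in epa.items()},
            },
        )


def _check_range(name: str, lo: float, hi: float) -> None:
    if hi < lo:
        raise ConfigurationError(f"range {name} has hi < lo: ({lo}, {hi})")


@dataclass(frozen=True)
class CohortHyper:
    """Cohort-level uniform ranges the per-subject profiles are drawn from.

    Defaults describe a healthy-control-like cohort: near-ceiling yes
    rates for jumps within ~200 ms of the press, near-floor rates beyond
    ~800 ms, and rare agency reports on beep-locked (EPA) jumps.
    """

    inflection_ms: tuple[float, float] = (300.0, 700.0)
    slope: tuple[float, float] = (0.010, 0.020)
    upper_asymptote: tuple[float, float] = (0.90, 1.00)
    lower_asymptote: tuple[float, float] = (0.00, 0.08)
    epa_yes_prob: tuple[float, float] = (0.10, 0.30)
    rt_mean_ms: tuple[float, float] = (250.0, 450.0)
    rt_sd_ms: tuple[float, float] = (30.0, 80.0)

    def __post_init__(self) -> None:
        for name in (
            "inflection_ms",
            "slope",
            "upper_asymptote",
            "lower_asymptote",
            "epa_yes_prob",
            "rt_mean_ms",
            "rt_sd_ms",
        ):
            _check_range(name, *getattr(self, name))
        if self.lower_asymptote[1] >= self.upper_asymptote[0]:
            raise ConfigurationError(
                "lower_asymptote range must lie strictly below upper_asymptote range"
            )
        if self.slope[0] <= 0:
            raise ConfigurationError("slope range must be positive")
        if self.rt_mean_ms[0] <= 0 or self.rt_sd_ms[0] < 0:
            raise ConfigurationError("reaction-time ranges must be positive")


DEFAULT_HYPER = CohortHyper()

#: Shifted ranges producing the paranoid-type signature: elevated floor
#: (agency still reported at long latencies) and high EPA yes rates.
PS_HYPER = CohortHyper(
    inflection_ms=(400.0, 800.0),
    slope=(0.008, 0.015),
    upper_asymptote=(0.90, 1.00),
    lower_asymptote=(0.40, 0.65),
    epa_yes_prob=(0.40, 0.70),
    rt_mean_ms=(250.0, 450.0),
    rt_sd_ms=(30.0, 80.0),
)

#: Shifted ranges producing the negative-symptom signature: depressed
#: ceiling (agency often denied even at zero latency).
NS_HYPER = CohortHyper(
    inflection_ms=(200.0, 500.0),
    slope=(0.010, 0.020),
    upper_asymptote=(0.45, 0.70),
    lower_asymptote=(0.00, 0.08),
    epa_yes_prob=(0.05, 0.20),
    rt_mean_ms=(250.0, 450.0),
    rt_sd_ms=(30.0, 80.0),
)


def generate_subject_profile(
    seed: "SeedLike",
    hyper: CohortHyper = DEFAULT_HYPER,
    subject_id: str = "S0",
) -> SubjectProfile:
    """Draw one subject's profile uniformly within the cohort ranges."""
    rng = np.random.default_rng(seed)
    u = lambda r: float(rng.uniform(*r)) if r[0] < r[1] else float(r[0])  # noqa: E731
    return SubjectProfile(
        subject_id=subject_id,
        inflection_ms=u(hyper.inflection_ms),
        slope=u(hyper.slope),
        upper_asymptote=u(hyper.upper_asymptote),
        lower_asymptote=u(hyper.lower_asymptote),
        epa_yes_prob=tuple(u(hyper.epa_yes_prob) for _ in EPA_OFFSETS_MS),
        rt_mean_ms=u(hyper.rt_mean_ms),
        rt_sd_ms=u(hyper.rt_sd_ms),
    )


def yes_probability(profile: SubjectProfile, trial_type: str, condition_ms: int) -> float:
    """Probability of a 'yes' (agency) report for one condition."""
    if trial_type == ACTION_LINKED:
        if condition_ms not in ACTION_LATENCIES_MS:
            raise ConfigurationError(f"unknown latency condition: {condition_ms}")
        lo, hi = profile.lower_asymptote, profile.upper_asymptote
        z = -profile.slope * (condition_ms - profile.inflection_ms)
        return float(lo + (hi - lo) * expit(z))
    if trial_type == EPA:
        if condition_ms not in EPA_OFFSETS_MS:
            raise ConfigurationError(f"unknown EPA offset: {condition_ms}")
        return float(profile.epa_yes_prob[EPA_OFFSETS_MS.index(condition_ms)])
    raise ConfigurationError(f"unknown trial type: {trial_type!r}")


def probability_curve(profile: SubjectProfile, n_trials: int = N_REPEATS_PER_CONDITION) -> YesRateCurve:
    """The profile's exact psychometric curve packaged as a YesRateCurve."""
    return YesRateCurve(
        action_rates={
            ms: yes_probability(profile, ACTION_LINKED, ms) for ms in ACTION_LATENCIES_MS
        },
        epa_rates={ms: yes_probability(profile, EPA, ms) for ms in EPA_OFFSETS_MS},
        n_per_condition={cond: n_trials for cond in
                         [(ACTION_LINKED, ms) for ms in ACTION_LATENCIES_MS]
                         + [(EPA, ms) for ms in EPA_OFFSETS_MS]},
    )


def sample_rt(profile: SubjectProfile, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Truncated-normal reaction times, strictly positive (>= 1 ms)."""
    out = rng.normal(profile.rt_mean_ms, profile.rt_sd_ms, size=size)
    bad = out < 1.0
    while np.any(bad):  # rejection sampling of the truncation tail
        out[bad] = rng.normal(profile.rt_mean_ms, profile.rt_sd_ms, size=int(bad.sum()))
        bad = out < 1.0
    return out


def generate_behavioral_dataset(profile: SubjectProfile, seed: "SeedLike") -> BehavioralDataset:
    """One synthetic session: 140 trials in seeded random order."""
    rng = np.random.default_rng(seed)
    conditions = [(ACTION_LINKED, ms) for ms in ACTION_LATENCIES_MS for _ in range(N_REPEATS_PER_CONDITION)]
    conditions += [(EPA, ms) for ms in EPA_OFFSETS_MS for _ in range(N_REPEATS_PER_CONDITION)]
    rts = sample_rt(profile, rng, size=len(conditions))
    trials = [
        Trial(
            trial_type=tt,
            condition_ms=ms,
            rt_ms=float(rt),
            response=int(rng.random() < yes_probability(profile, tt, ms)),
        )
        for (tt, ms), rt in zip(conditions, rts)
    ]
    order = rng.permutation(len(trials))  # random mixture of action-linked and EPA
    return BehavioralDataset(
        subject_id=profile.subject_id,
        trials=tuple(trials[i] for i in order),
        profile=profile,
    )


def generate_cohort(
    n_subjects: int = 17,
    seed: int = 0,
    hyper: CohortHyper = DEFAULT_HYPER,
) -> list[BehavioralDataset]:
    """Independent synthetic H-subjects (default cohort size 17)."""
    if n_subjects < 1:
        raise ConfigurationError(f"n_subjects must be >= 1, got {n_subjects}")
    cohort = []
    for i in range(n_subjects):
        profile = generate_subject_profile(
            subject_seed(seed, i, 0), hyper, subject_id=f"H{i:02d}"
        )
        cohort.append(generate_behavioral_dataset(profile, subject_seed(seed, i, 1)))
    return cohort


def generate_sz_reference(
    group: str = "mixed",
    n_subjects: int | None = None,
    seed: int = 0,
    ps_hyper: CohortHyper = PS_HYPER,
    ns_hyper: CohortHyper = NS_HYPER,
) -> list[YesRateCurve]:
    """Synthetic schizophrenia-pattern reference yes-rate curves.

    ``group`` is ``"PS"`` (default 30 curves), ``"NS"`` (default 20) or
    ``"mixed"`` (30 PS followed by 20 NS). The curves are the exact
    psychometric probabilities of profiles drawn from the shifted
    parameter ranges — qualitative stand-ins for undeposited patient
    data, not ground truth.
    """
    if group == "mixed":
        if n_subjects is not None and n_subjects != 50:
            raise ConfigurationError("mixed group uses the fixed 30 PS + 20 NS composition")
        return generate_sz_reference("PS", 30, seed, ps_hyper, ns_hyper) + generate_sz_reference(
            "NS", 20, seed, ps_hyper, ns_hyper
        )
    if group == "PS":
        hyper, n_default, tag = ps_hyper, 30, "PS"
    elif group == "NS":
        hyper, n_default, tag = ns_hyper, 20, "NS"
    else:
        raise ConfigurationError(f"unknown group label: {group!r}")
    n = n_default if n_subjects is None else int(n_subjects)
    if n < 1:
        raise ConfigurationError(f"n_subjects must be >= 1, got {n}")
    curves = []
    for i in range(n):
        profile = generate_subject_profile(
            np.random.SeedSequence([int(seed), {"PS": 1, "NS": 2}[tag], i]),
            hyper,
            subject_id=f"{tag}{i:02d}",
        )
        curves.append(probability_curve(profile))
    return curves


def default_profile(subject_id: str = "HC-default") -> SubjectProfile:
    """Profile at the midpoint of every default healthy-cohort range."""
    h = DEFAULT_HYPER
    mid = lambda r: 0.5 * (r[0] + r[1])  # noqa: E731
    return SubjectProfile(
        subject_id=subject_id,
        inflection_ms=mid(h.inflection_ms),
        slope=mid(h.slope),
        upper_asymptote=mid(h.upper_asymptote),
        lower_asymptote=mid(h.lower_asymptote),
        epa_yes_prob=tuple(mid(h.epa_yes_prob) for _ in EPA_OFFSETS_MS),
        rt_mean_ms=mid(h.rt_mean_ms),
        rt_sd_ms=mid(h.rt_sd_ms),
    )
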