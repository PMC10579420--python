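"""Simulated lesions applied to trained model subjects at test time.

Five manipulations, none of which touches the trained weights:

- ``td_context``: the recurrent read c_k(t-1) becomes c_k(t-1-Delta),
  Delta in {0,1} resampled per receiving context unit per step. This is
  the temporal-delay-in-prediction hypothesis lesion.
- ``noise``: the membrane potential is multiplied by (1 + noise) each
  step, noise drawn at amplitude ``noise_level`` (default 0.01).
- ``td_output``: only the agency output unit reads c(t-1-Delta), one
  Delta per step.
- ``td_input``: the input read x_j(t) becomes x_j(t-Delta), Delta per
  input unit per step.
- ``reduced_gain``: the sigmoid gain a is replaced everywhere
  (candidate values 0.99, 0.9, 0.5).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import SensorimotorSequence, stack_inputs
from .errors import ConfigurationError
from .evaluation import YesRateCurve, yes_rate_curve
from .rnn import RNNParams, run_batch

LESION_KINDS = ("none", "td_context", "noise", "td_output", "td_input", "reduced_gain")

#: Maximum temporal delay, in steps. The model applies delays only in
#: one-step increments.
DELTA_MAX = 1


@dataclass(frozen=True)
class LesionConfig:
    kind: str = "none"
    delta_prob: float = 0.5  # P(Delta = 1) per draw
    noise_level: float = 0.01
    noise_dist: str = "uniform"  # uniform on [-level, level] or gaussian SD=level
    gain_value: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ConfigurationError(f"unknown lesion kind: {self.kind!r}")
        if not 0.0 <= self.delta_prob <= 1.0:
            raise ConfigurationError(f"delta_prob out of [0,1]: {self.delta_prob}")
        if self.noise_level < 0:
            raise ConfigurationError(f"noise_level must be >= 0: {self.noise_level}")
        if self.noise_dist not in ("uniform", "gaussian"):
            raise ConfigurationError(f"unknown noise_dist: {self.noise_dist!r}")
        if self.kind == "reduced_gain":
            if self.gain_value is None:
                raise ConfigurationError("reduced_gain lesion requires gain_value")
            if self.gain_value <= 0:
                raise ConfigurationError(f"gain_value must be > 0: {self.gain_value}")


HEALTHY = LesionConfig(kind="none")


@dataclass(frozen=True)
class LesionedDynamics:
    """A validated (params, lesion) pair ready to run."""

    params: RNNParams
    lesion: LesionConfig

    def run(self, sequences: list[SensorimotorSequence], rng=None):
        X = stack_inputs(sequences)
        if rng is None and self.lesion.kind != "none":
            rng = np.random.default_rng(self.lesion.seed)
        return run_batch(self.params, X, self.lesion, rng)


@dataclass(frozen=True)
class LesionRunResult:
    m_subject_id: str
    lesion: LesionConfig
    yes_rate_curve: YesRateCurve
    healthy_curve: YesRateCurve


def apply_lesion(params: RNNParams, lesion: LesionConfig) -> LesionedDynamics:
    """Package a trained model with a lesion; weights stay untouched."""
    return LesionedDynamics(params=params, lesion=lesion)


def model_curve(
    params: RNNParams,
    test_set: list[SensorimotorSequence],
    lesion: LesionConfig = HEALTHY,
    rng: np.random.Generator | None = None,
) -> YesRateCurve:
    """Yes-rate curve of one model on a test set (lesioned or not)."""
    result = apply_lesion(params, lesion).run(test_set, rng)
    return yes_rate_curve(
        result.final_soa,
        [s.trial_type for s in test_set],
        np.array([s.condition_ms for s in test_set]),
    )


def run_lesion_experiment(
    m_subjects,
    test_sets: dict[str, list[SensorimotorSequence]],
    lesion: LesionConfig,
    healthy_curves: dict[str, YesRateCurve] | None = None,
) -> list[LesionRunResult]:
    """Run one lesion over a cohort of trained model subjects.

    ``test_sets`` maps m_subject_id to that subject's test sequences;
    ``healthy_curves`` may carry cached unlesioned baselines (computed
    here when absent). Each subject's lesion RNG stream is derived from
    ``lesion.seed`` and the subject id, independent of the training and
    behavior streams.
    """
    healthy_curves = dict(healthy_curves or {})
    results = []
    for m in m_subjects:
        sid = m.m_subject_id
        test_set = test_sets[sid]
        if sid not in healthy_curves:
            healthy_curves[sid] = model_curve(m.params, test_set, HEALTHY)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(lesion.seed), *map(ord, sid)])
        )
        lesioned = model_curve(m.params, test_set, lesion, rng)
        results.append(
            LesionRunResult(
                m_subject_id=sid,
                lesion=lesion,
                yes_rate_curve=lesioned,
                healthy_curve=healthy_curves[sid],
            )
        )
    return results
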