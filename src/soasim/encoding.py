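"""Encoding of task trials as time-indexed sensorimotor sequences.

A trial becomes a fixed-length sequence of three input channels (beep,
button press, object position) and four target channels (one-step
predictions of the three inputs plus the agency judgment). All channel
values live in [0.1, 0.9]: event channels are 0.9 during the event and
0.1 otherwise, the position channel ramps monotonically from 0.1 to 0.9
with an extra one-step increment at the jump, and the judgment channel
ramps linearly from the neutral 0.5 to 0.9 (yes) or 0.1 (no).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .behavior import BehavioralDataset, SubjectProfile, Trial, sample_rt
from .constants import (
    ACTION_LATENCIES_MS,
    ACTION_LINKED,
    EPA,
    EPA_OFFSETS_MS,
)
from .errors import ConfigurationError, EncodingError

LO, HI = 0.1, 0.9
NEUTRAL_SOA = 0.5

#: Channel order shared with the network: inputs and the first three
#: targets are [beep, button, position]; target 3 is the SoA judgment.
CH_BEEP, CH_BUTTON, CH_POSITION, CH_SOA = 0, 1, 2, 3


@dataclass(frozen=True)
class EncodingConfig:
    """Timing layout of one encoded trial.

    30 steps of 100 ms give a 3 s trial: long enough for the beep (step
    5), the slowest plausible reaction time, a 1000 ms jump latency and
    a settling window before the final judgment readout.
    """

    dt_ms: float = 100.0
    n_steps: int = 30
    beep_onset_step: int = 5
    beep_width_steps: int = 1
    jump_increment: float = 0.2  # pre-normalization bump at the jump step
    #: "post_jump" holds the judgment target at the neutral 0.5 until
    #: the piece jumps, then ramps linearly to the final value — before
    #: the jump, trials of different conditions are indistinguishable,
    #: so an earlier ramp would demand divergent outputs on identical
    #: prefixes. "full" ramps linearly over the whole trial instead.
    soa_ramp: str = "post_jump"

    def __post_init__(self) -> None:
        if self.soa_ramp not in ("post_jump", "full"):
            raise ConfigurationError(f"unknown soa_ramp: {self.soa_ramp!r}")
        if self.dt_ms <= 0 or 100.0 % self.dt_ms != 0:
            raise ConfigurationError(f"dt_ms must divide 100 ms: {self.dt_ms}")
        if self.n_steps < 4:
            raise ConfigurationError("n_steps too small to hold a trial")
        if not 0 <= self.beep_onset_step < self.n_steps:
            raise ConfigurationError("beep_onset_step outside the sequence")
        if self.beep_width_steps < 1:
            raise ConfigurationError("beep_width_steps must be >= 1")
        if self.jump_increment < 0:
            raise ConfigurationError("jump_increment must be >= 0")


DEFAULT_ENCODING = EncodingConfig()


@dataclass(frozen=True)
class SensorimotorSequence:
    inputs: np.ndarray  # (T, 3) in [0.1, 0.9]
    targets: np.ndarray | None  # (T, 4); None for test sequences
    event_times: dict  # step indices: beep, press, jump
    trial_type: str
    condition_ms: int
    dt_ms: float
    sequence_id: str = ""

    @property
    def length(self) -> int:
        return int(self.inputs.shape[0])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def encode_trial(
    trial: Trial,
    response: int | None,
    enc: EncodingConfig = DEFAULT_ENCODING,
    sequence_id: str = "",
) -> SensorimotorSequence:
    """Encode one trial; ``response=None`` leaves the judgment target out.

    The button press lands at ``beep_onset + round(rt/dt)``; the piece
    jumps at ``press + latency/dt`` (action-linked) or ``beep +
    offset/dt`` (EPA).
    """
    T = enc.n_steps
    press_step = enc.beep_onset_step + _round_half_up(trial.rt_ms / enc.dt_ms)
    if trial.trial_type == ACTION_LINKED:
        jump_step = press_step + int(round(trial.condition_ms / enc.dt_ms))
    else:
        jump_step = enc.beep_onset_step + int(round(trial.condition_ms / enc.dt_ms))
    for name, step in (("press", press_step), ("jump", jump_step)):
        if not 0 <= step < T:
            raise EncodingError(
                f"{name} event at step {step} falls outside the {T}-step window "
                f"(rt={trial.rt_ms} ms, condition={trial.condition_ms} ms)"
            )

    inputs = np.full((T, 3), LO)
    beep_end = min(enc.beep_onset_step + enc.beep_width_steps, T)
    inputs[enc.beep_onset_step:beep_end, CH_BEEP] = HI
    inputs[press_step, CH_BUTTON] = HI

    # Monotone position ramp with a one-step jump increment, scaled so
    # the endpoint is exactly HI.
    increments = np.full(T, (HI - LO) / (T - 1))
    increments[0] = 0.0
    if jump_step > 0:
        increments[jump_step] += enc.jump_increment
    else:
        increments[1] += enc.jump_increment  # jump at t=0 folds into the first step
    increments *= (HI - LO) / increments.sum()
    position = LO + np.cumsum(increments)
    inputs[:, CH_POSITION] = position

    targets = None
    if response is not None:
        targets = np.empty((T, 4))
        targets[:, :3] = inputs
        end_val = HI if response else LO
        if enc.soa_ramp == "post_jump":
            soa = np.full(T, NEUTRAL_SOA)
            soa[jump_step:] = np.linspace(NEUTRAL_SOA, end_val, T - jump_step)
            targets[:, CH_SOA] = soa
        else:
            targets[:, CH_SOA] = np.linspace(NEUTRAL_SOA, end_val, T)

    return SensorimotorSequence(
        inputs=inputs,
        targets=targets,
        event_times={"beep": enc.beep_onset_step, "press": press_step, "jump": jump_step},
        trial_type=trial.trial_type,
        condition_ms=trial.condition_ms,
        dt_ms=enc.dt_ms,
        sequence_id=sequence_id,
    )


def decode_events(seq: SensorimotorSequence) -> dict:
    """Recover event steps from the channels alone (round-trip check)."""
    beep = int(np.argmax(seq.inputs[:, CH_BEEP]))
    press = int(np.argmax(seq.inputs[:, CH_BUTTON]))
    steps = np.diff(seq.inputs[:, CH_POSITION])
    jump = int(np.argmax(steps)) + 1 if steps.size else 0
    return {"beep": beep, "press": press, "jump": jump}


def build_training_set(
    dataset: BehavioralDataset, enc: EncodingConfig = DEFAULT_ENCODING
) -> list[SensorimotorSequence]:
    """One target-bearing sequence per recorded trial (140 per subject)."""
    out = []
    for i, trial in enumerate(dataset.trials):
        try:
            out.append(
                encode_trial(
                    trial,
                    trial.response,
                    enc,
                    sequence_id=f"{dataset.subject_id}-train-{i:03d}",
                )
            )
        except EncodingError as err:
            raise EncodingError(f"trial {i} of {dataset.subject_id}: {err}") from err
    return out


def build_test_set(
    profile: SubjectProfile,
    n_per_condition: int = 100,
    seed: "int | np.random.SeedSequence" = 0,
    enc: EncodingConfig = DEFAULT_ENCODING,
) -> list[SensorimotorSequence]:
    """Shuffled test sequences with freshly resampled reaction times.

    ``n_per_condition`` sequences for each of the 14 conditions (default
    100, i.e. 1400 sequences). Test sequences carry no judgment target;
    the model's output is read instead.
    """
    if n_per_condition < 1:
        raise ConfigurationError(f"n_per_condition must be >= 1: {n_per_condition}")
    rng = np.random.default_rng(seed)
    conditions = [(ACTION_LINKED, ms) for ms in ACTION_LATENCIES_MS]
    conditions += [(EPA, ms) for ms in EPA_OFFSETS_MS]
    seqs = []
    for tt, ms in conditions:
        rts = sample_rt(profile, rng, size=n_per_condition)
        for r, rt in enumerate(rts):
            trial = Trial(trial_type=tt, condition_ms=ms, rt_ms=float(rt), response=0)
            seqs.append(
                encode_trial(
                    trial, None, enc, sequence_id=f"{profile.subject_id}-test-{tt}-{ms}-{r:03d}"
                )
            )
    order = rng.permutation(len(seqs))
    return [seqs[i] for i in order]


CHANNEL_NAMES = ("beep", "button", "position", "soa_target")


def sequence_rows(seq: SensorimotorSequence) -> list[dict]:
    """Long-format records (sequence_id, t, channel, value) for CSV
    inspection; target channels carry a ``target_`` prefix."""
    rows = []
    for t in range(seq.length):
        for ch in range(3):
            rows.append(
                {"sequence_id": seq.sequence_id, "t": t,
                 "channel": CHANNEL_NAMES[ch], "value": float(seq.inputs[t, ch])}
            )
        if seq.targets is not None:
            for ch in range(4):
                rows.append(
                    {"sequence_id": seq.sequence_id, "t": t,
                     "channel": f"target_{CHANNEL_NAMES[ch]}",
                     "value": float(seq.targets[t, ch])}
                )
    return rows


def stack_inputs(seqs: list[SensorimotorSequence]) -> np.ndarray:
    """(N, T, 3) input tensor; all sequences must share a length."""
    lengths = {s.length for s in seqs}
    if len(lengths) != 1:
        raise EncodingError(f"sequences have mixed lengths: {sorted(lengths)}")
    return np.stack([s.inputs for s in seqs])


def stack_targets(seqs: list[SensorimotorSequence]) -> np.ndarray:
    """(N, T, 4) target tensor for training sequences."""
    if any(s.targets is None for s in seqs):
        raise EncodingError("some sequences carry no targets (test sequences?)")
    return np.stack([s.targets for s in seqs])
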