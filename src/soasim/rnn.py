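"""Continuous-time recurrent network for sensorimotor prediction.

The model is a leaky-integrator firing-rate network. Context-unit
membrane potentials follow

    u_i(t) = (1 - 1/tau) u_i(t-1)
             + (1/tau) [ sum_j W_cx[i,j] x_j(t) + sum_k W_cc[i,k] c_k(t-1) ],
    c_i(t) = f(u_i(t)),          f(u) = 1 / (1 + exp(-a u)),

with time constant ``tau`` (default 10.0) and sigmoid gain ``a``
(default 1.0). Output units read the context layer one step back:

    o_i(t) = f( sum_j W_oc[i,j] c_j(t-1) ).

Input and output units connect only via the ten context units; there
are no direct input-to-output weights and no bias terms. Lesion hooks
cover random one-step temporal delays on the recurrent, input or
agency-output reads, multiplicative state noise, and a reduced sigmoid
gain; weights are never modified by a lesion.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .encoding import SensorimotorSequence
from .errors import ConfigurationError

N_CONTEXT = 10
N_INPUT = 3
N_OUTPUT = 4
SOA_OUTPUT = 3  # index of the agency-judgment output unit

#: Boundary values for reads before the first step: context activations
#: sit at f(0) = 0.5 and input channels at their 0.1 baseline.
C_INIT = 0.5
X_INIT = 0.1


@dataclass
class RNNParams:
    W_cx: np.ndarray  # (10, 3) context <- input
    W_cc: np.ndarray  # (10, 10) context <- context (self-connections included)
    W_oc: np.ndarray  # (4, 10) output <- context
    tau: float = 10.0
    gain: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W_cx = np.asarray(self.W_cx, dtype=float)
        self.W_cc = np.asarray(self.W_cc, dtype=float)
        self.W_oc = np.asarray(self.W_oc, dtype=float)
        shapes = (self.W_cx.shape, self.W_cc.shape, self.W_oc.shape)
        expected = ((N_CONTEXT, N_INPUT), (N_CONTEXT, N_CONTEXT), (N_OUTPUT, N_CONTEXT))
        if shapes != expected:
            raise ConfigurationError(f"weight shapes {shapes} != {expected}")
        if not all(np.all(np.isfinite(w)) for w in (self.W_cx, self.W_cc, self.W_oc)):
            raise ConfigurationError("weights must be finite")
        if self.tau < 1.0:
            raise ConfigurationError(f"tau must be >= 1: {self.tau}")
        if self.gain <= 0.0:
            raise ConfigurationError(f"gain must be > 0: {self.gain}")

    @classmethod
    def init_random(
        cls,
        rng: np.random.Generator,
        scale: float = 0.1,
        tau: float = 10.0,
        gain: float = 1.0,
        metadata: dict | None = None,
    ) -> "RNNParams":
        """Weights uniform in [-scale, scale]."""
        return cls(
            W_cx=rng.uniform(-scale, scale, (N_CONTEXT, N_INPUT)),
            W_cc=rng.uniform(-scale, scale, (N_CONTEXT, N_CONTEXT)),
            W_oc=rng.uniform(-scale, scale, (N_OUTPUT, N_CONTEXT)),
            tau=tau,
            gain=gain,
            metadata=metadata or {},
        )

    def copy(self) -> "RNNParams":
        return RNNParams(
            self.W_cx.copy(), self.W_cc.copy(), self.W_oc.copy(),
            self.tau, self.gain, dict(self.metadata),
        )

    # -- plain-text serialization (bit-exact round trip) ----------------
    def to_json(self) -> str:
        payload = {
            "format": "soasim-rnn-v1",
            "tau": self.tau,
            "gain": self.gain,
            "W_cx": self.W_cx.tolist(),
            "W_cc": self.W_cc.tolist(),
            "W_oc": self.W_oc.tolist(),
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RNNParams":
        d = json.loads(text)
        if d.get("format") != "soasim-rnn-v1":
            raise ConfigurationError(f"unknown weight-file format: {d.get('format')!r}")
        return cls(
            W_cx=np.array(d["W_cx"]), W_cc=np.array(d["W_cc"]), W_oc=np.array(d["W_oc"]),
            tau=float(d["tau"]), gain=float(d["gain"]), metadata=d.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "RNNParams":
        return cls.from_json(Path(path).read_text())


def activation(u, gain: float = 1.0):
    """Sigmoid f(u) = 1 / (1 + exp(-gain * u))."""
    return expit(gain * np.asarray(u, dtype=float))


def _effective_gain(params: RNNParams, lesion) -> float:
    if lesion is not None and lesion.kind == "reduced_gain":
        return float(lesion.gain_value)
    return params.gain


def _lesion_kind(lesion) -> str:
    return "none" if lesion is None else lesion.kind


def _noise_draw(lesion, rng: np.random.Generator, shape):
    if lesion.noise_dist == "uniform":
        return rng.uniform(-lesion.noise_level, lesion.noise_level, shape)
    return rng.normal(0.0, lesion.noise_level, shape)


@dataclass
class RNNState:
    """Single-sequence dynamical state with the short history the
    one-step delay lesions need."""

    u: np.ndarray  # (10,) membrane potentials u(t)
    c_prev: np.ndarray  # c(t-1)
    c_prev2: np.ndarray  # c(t-2)
    x_prev: np.ndarray  # x(t-1)
    t: int = 0


def init_state() -> RNNState:
    return RNNState(
        u=np.zeros(N_CONTEXT),
        c_prev=np.full(N_CONTEXT, C_INIT),
        c_prev2=np.full(N_CONTEXT, C_INIT),
        x_prev=np.full(N_INPUT, X_INIT),
    )


def read_outputs(
    state: RNNState,
    params: RNNParams,
    lesion=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """o(t) = f(W_oc c(t-1)); under the output-delay lesion only the
    agency unit reads c(t-1-Delta), Delta in {0,1} resampled per step."""
    gain = _effective_gain(params, lesion)
    uo = params.W_oc @ state.c_prev
    if _lesion_kind(lesion) == "td_output":
        if rng.random() < lesion.delta_prob:
            uo[SOA_OUTPUT] = params.W_oc[SOA_OUTPUT] @ state.c_prev2
    return activation(uo, gain)


def step(
    state: RNNState,
    x_t: np.ndarray,
    params: RNNParams,
    lesion=None,
    rng: np.random.Generator | None = None,
) -> RNNState:
    """Advance the leaky-integrator dynamics by one step (with lesions)."""
    kind = _lesion_kind(lesion)
    gain = _effective_gain(params, lesion)
    x_t = np.asarray(x_t, dtype=float)

    if kind == "td_input":
        delta = rng.random(N_INPUT) < lesion.delta_prob
        x_eff = np.where(delta, state.x_prev, x_t)
    else:
        x_eff = x_t

    if kind == "td_context":
        # Delay indexed per receiving unit: unit i reads every source
        # activation at t-1-Delta_i, Delta_i resampled each step.
        delta = rng.random(N_CONTEXT) < lesion.delta_prob
        rec = np.where(delta, params.W_cc @ state.c_prev2, params.W_cc @ state.c_prev)
    else:
        rec = params.W_cc @ state.c_prev

    inv_tau = 1.0 / params.tau
    u = (1.0 - inv_tau) * state.u + inv_tau * (params.W_cx @ x_eff + rec)
    if kind == "noise":
        u = u * (1.0 + _noise_draw(lesion, rng, N_CONTEXT))
    c = activation(u, gain)
    return RNNState(u=u, c_prev=c, c_prev2=state.c_prev, x_prev=x_t, t=state.t + 1)


@dataclass
class Trajectory:
    """Per-step records of one sequence run."""

    u: np.ndarray  # (T, 10)
    c: np.ndarray  # (T, 10)
    o: np.ndarray  # (T, 4); o[t] reads c(t-1)
    final_soa: float
    trial_type: str = ""
    condition_ms: int = 0
    jump_step: int = -1


def run_sequence(
    params: RNNParams,
    seq: SensorimotorSequence,
    lesion=None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Open-loop run: the task's sensory channels drive the network at
    every step; outputs are one-step predictions plus the agency
    judgment read at the final step."""
    T = seq.length
    if T == 0:
        raise ConfigurationError("cannot run a length-0 sequence")
    if _lesion_kind(lesion) != "none" and rng is None:
        rng = np.random.default_rng(lesion.seed)
    state = init_state()
    u_rec = np.empty((T, N_CONTEXT))
    c_rec = np.empty((T, N_CONTEXT))
    o_rec = np.empty((T, N_OUTPUT))
    for t in range(T):
        o_rec[t] = read_outputs(state, params, lesion, rng)
        state = step(state, seq.inputs[t], params, lesion, rng)
        u_rec[t] = state.u
        c_rec[t] = state.c_prev
    return Trajectory(
        u=u_rec,
        c=c_rec,
        o=o_rec,
        final_soa=float(o_rec[-1, SOA_OUTPUT]),
        trial_type=seq.trial_type,
        condition_ms=seq.condition_ms,
        jump_step=seq.event_times.get("jump", -1),
    )


@dataclass
class BatchResult:
    o: np.ndarray  # (N, T, 4)
    c: np.ndarray  # (N, T, 10); c[:, t] = c(t)
    u: np.ndarray  # (N, T, 10)

    @property
    def final_soa(self) -> np.ndarray:
        return self.o[:, -1, SOA_OUTPUT]


def run_batch(
    params: RNNParams,
    X: np.ndarray,
    lesion=None,
    rng: np.random.Generator | None = None,
) -> BatchResult:
    """Vectorized forward pass over N equal-length sequences.

    Lesion draws are independent across sequences, units and steps. The
    per-step draw order (output delay, input delay, context delay,
    noise) matches :func:`read_outputs` / :func:`step`, so a batch of
    one sequence consumes the generator stream identically to the
    sequential API.
    """
    X = np.asarray(X, dtype=float)
    N, T, _ = X.shape
    if T == 0:
        raise ConfigurationError("cannot run length-0 sequences")
    kind = _lesion_kind(lesion)
    if kind != "none" and rng is None:
        rng = np.random.default_rng(lesion.seed)
    gain = _effective_gain(params, lesion)
    inv_tau = 1.0 / params.tau
    leak = 1.0 - inv_tau

    u = np.zeros((N, N_CONTEXT))
    c_prev = np.full((N, N_CONTEXT), C_INIT)
    c_prev2 = np.full((N, N_CONTEXT), C_INIT)
    x_prev = np.full((N, N_INPUT), X_INIT)
    o_rec = np.empty((N, T, N_OUTPUT))
    c_rec = np.empty((N, T, N_CONTEXT))
    u_rec = np.empty((N, T, N_CONTEXT))

    for t in range(T):
        uo = c_prev @ params.W_oc.T
        if kind == "td_output":
            delayed = rng.random(N) < lesion.delta_prob
            uo[:, SOA_OUTPUT] = np.where(
                delayed, c_prev2 @ params.W_oc[SOA_OUTPUT], uo[:, SOA_OUTPUT]
            )
        o_rec[:, t] = activation(uo, gain)

        x_t = X[:, t]
        if kind == "td_input":
            delta = rng.random((N, N_INPUT)) < lesion.delta_prob
            x_eff = np.where(delta, x_prev, x_t)
        else:
            x_eff = x_t
        if kind == "td_context":
            delta = rng.random((N, N_CONTEXT)) < lesion.delta_prob
            rec = np.where(delta, c_prev2 @ params.W_cc.T, c_prev @ params.W_cc.T)
        else:
            rec = c_prev @ params.W_cc.T
        u = leak * u + inv_tau * (x_eff @ params.W_cx.T + rec)
        if kind == "noise":
            u = u * (1.0 + _noise_draw(lesion, rng, (N, N_CONTEXT)))
        c = activation(u, gain)
        u_rec[:, t] = u
        c_rec[:, t] = c
        c_prev2, c_prev, x_prev = c_prev, c, x_t
    return BatchResult(o=o_rec, c=c_rec, u=u_rec)
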