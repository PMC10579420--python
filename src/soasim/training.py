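"""Backpropagation-through-time training of model subjects.

Each synthetic H-subject's 140 encoded trials are fit in batch mode by
full-unroll gradient descent with momentum on the summed squared error
between the four output channels and their targets. A trained replicate
("M-subject") is then checked for behavioral reproduction: the root
mean square difference between the subject's empirical per-condition
yes rates and the model's yes rates, on the training sequences
(training error) and on a freshly sampled test set (generalization
error).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .behavior import BehavioralDataset
from .encoding import (
    DEFAULT_ENCODING,
    EncodingConfig,
    SensorimotorSequence,
    build_training_set,
    stack_inputs,
    stack_targets,
)
from .errors import ConfigurationError, TrainingDivergenceError
from .evaluation import YesRateCurve, curve_rmse, mann_whitney_u, yes_rate_curve
from .rnn import C_INIT, N_CONTEXT, RNNParams, run_batch

try:  # compiled training kernel; the numpy path remains the reference
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class TrainingConfig:
    optimizer: str = "adam"  # "adam" or "momentum"
    learning_rate: float = 0.02
    momentum: float = 0.9
    epochs: int = 25000
    weight_init_scale: float = 0.1
    #: The judgment channel is weighted 3x so the single agency output
    #: balances the three sensory-prediction outputs.
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 3.0)
    stop_tolerance: float = 0.0  # early stop when |loss change| falls below
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "momentum"):
            raise ConfigurationError(f"unknown optimizer: {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigurationError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.weight_init_scale <= 0:
            raise ConfigurationError("weight_init_scale must be > 0")
        if any(w < 0 for w in self.loss_weights) or len(self.loss_weights) != 4:
            raise ConfigurationError("loss_weights must be 4 non-negative values")


@dataclass
class MSubject:
    m_subject_id: str
    params: RNNParams
    source_subject_id: str
    replicate_index: int  # 1-based
    training_error: float | None = None
    generalization_error: float | None = None
    reproduction_pass: bool | None = None


def loss_and_gradients(
    params: RNNParams, X: np.ndarray, Y: np.ndarray, loss_weights
) -> tuple[float, dict[str, np.ndarray]]:
    """Batch loss (mean over sequences, summed over steps/channels) and
    its exact BPTT gradients."""
    w = np.asarray(loss_weights, dtype=float)
    N, T, _ = X.shape
    res = run_batch(params, X)
    o, c = res.o, res.c
    a = params.gain
    inv_tau = 1.0 / params.tau
    leak = 1.0 - inv_tau

    err = o - Y
    loss = float(np.sum(w * err**2) / N)

    # c(t-1) for every step t, with the 0.5 boundary at t=0.
    c_prev = np.concatenate([np.full((N, 1, N_CONTEXT), C_INIT), c[:, :-1]], axis=1)
    duo = (2.0 / N) * w * err * a * o * (1.0 - o)  # dL/du_out (N,T,4)
    gW_oc = np.einsum("nti,ntj->ij", duo, c_prev)

    # dL/dc(t) contributed by the outputs at step t+1.
    dc_from_out = duo @ params.W_oc  # (N,T,10), indexed by the *reading* step
    gW_cc = np.zeros_like(params.W_cc)
    gW_cx = np.zeros_like(params.W_cx)
    du_next = np.zeros((N, N_CONTEXT))
    for t in range(T - 1, -1, -1):
        dc_t = inv_tau * (du_next @ params.W_cc)
        if t + 1 < T:
            dc_t = dc_t + dc_from_out[:, t + 1]
        du_t = dc_t * a * c[:, t] * (1.0 - c[:, t]) + leak * du_next
        gW_cc += inv_tau * du_t.T @ c_prev[:, t]
        gW_cx += inv_tau * du_t.T @ X[:, t]
        du_next = du_t
    return loss, {"W_cx": gW_cx, "W_cc": gW_cc, "W_oc": gW_oc}


def _kernel_impl(W_cx, W_cc, W_oc, XT, YT, w, a, tau):
    """Fused forward + backward over (T, N, channels) tensors.

    Mirrors :func:`loss_and_gradients`; written as explicit loops so the
    compiled path avoids BLAS-call overhead on these tiny matrices.
    """
    T, N, n_in = XT.shape
    n_out = YT.shape[2]
    n_ctx = W_cc.shape[0]
    inv_tau = 1.0 / tau
    leak = 1.0 - inv_tau
    cs = np.empty((T, N, n_ctx))
    os_ = np.empty((T, N, n_out))
    c_prev = np.full((N, n_ctx), 0.5)
    u = np.zeros((N, n_ctx))
    for t in range(T):
        for n in range(N):
            for i in range(n_out):
                s = 0.0
                for j in range(n_ctx):
                    s += W_oc[i, j] * c_prev[n, j]
                os_[t, n, i] = 1.0 / (1.0 + np.exp(-a * s))
            for i in range(n_ctx):
                s = 0.0
                for j in range(n_in):
                    s += W_cx[i, j] * XT[t, n, j]
                for k in range(n_ctx):
                    s += W_cc[i, k] * c_prev[n, k]
                u[n, i] = leak * u[n, i] + inv_tau * s
        for n in range(N):
            for i in range(n_ctx):
                c_prev[n, i] = 1.0 / (1.0 + np.exp(-a * u[n, i]))
        cs[t] = c_prev

    loss = 0.0
    duo = np.empty_like(os_)
    for t in range(T):
        for n in range(N):
            for i in range(n_out):
                err = os_[t, n, i] - YT[t, n, i]
                loss += w[i] * err * err
                duo[t, n, i] = (2.0 / N) * w[i] * err * a * os_[t, n, i] * (1.0 - os_[t, n, i])
    loss /= N

    gW_oc = np.zeros_like(W_oc)
    gW_cc = np.zeros_like(W_cc)
    gW_cx = np.zeros_like(W_cx)
    du_next = np.zeros((N, n_ctx))
    dc_t = np.empty((N, n_ctx))
    for t in range(T - 1, -1, -1):
        for n in range(N):
            for k in range(n_ctx):
                s = 0.0
                for i in range(n_ctx):
                    s += du_next[n, i] * W_cc[i, k]
                s *= inv_tau
                if t + 1 < T:
                    for i in range(n_out):
                        s += duo[t + 1, n, i] * W_oc[i, k]
                dc_t[n, k] = s
        for n in range(N):
            for i in range(n_out):
                d = duo[t, n, i]
                if t > 0:
                    for j in range(n_ctx):
                        gW_oc[i, j] += d * cs[t - 1, n, j]
                else:
                    for j in range(n_ctx):
                        gW_oc[i, j] += d * 0.5
            for i in range(n_ctx):
                du = dc_t[n, i] * a * cs[t, n, i] * (1.0 - cs[t, n, i]) + leak * du_next[n, i]
                du_next[n, i] = du
                g = inv_tau * du
                if t > 0:
                    for k in range(n_ctx):
                        gW_cc[i, k] += g * cs[t - 1, n, k]
                else:
                    for k in range(n_ctx):
                        gW_cc[i, k] += g * 0.5
                for j in range(n_in):
                    gW_cx[i, j] += g * XT[t, n, j]
    return loss, gW_cx, gW_cc, gW_oc


if _HAVE_NUMBA:
    _kernel_fast = numba.njit(_kernel_impl, cache=False, fastmath=True)
else:  # pragma: no cover
    _kernel_fast = _kernel_impl


def _loss_and_gradients_fast(params, XT, YT, loss_weights):
    loss, gW_cx, gW_cc, gW_oc = _kernel_fast(
        params.W_cx, params.W_cc, params.W_oc, XT, YT,
        np.asarray(loss_weights, dtype=float), params.gain, params.tau,
    )
    return loss, {"W_cx": gW_cx, "W_cc": gW_cc, "W_oc": gW_oc}


def train_bptt(
    sequences: list[SensorimotorSequence],
    cfg: TrainingConfig,
    metadata: dict | None = None,
) -> RNNParams:
    """Fit one network to a batch of target-bearing sequences."""
    if not sequences:
        raise ConfigurationError("need at least one training sequence")
    X = stack_inputs(sequences)
    Y = stack_targets(sequences)
    XT = np.ascontiguousarray(X.transpose(1, 0, 2))
    YT = np.ascontiguousarray(Y.transpose(1, 0, 2))
    rng = np.random.default_rng(cfg.seed)
    params = RNNParams.init_random(
        rng, scale=cfg.weight_init_scale, metadata=dict(metadata or {}, training_seed=cfg.seed)
    )
    keys = ("W_cx", "W_cc", "W_oc")
    vel = {k: np.zeros_like(getattr(params, k)) for k in keys}
    second = {k: np.zeros_like(getattr(params, k)) for k in keys}
    b2, eps = 0.999, 1e-8
    prev_loss = np.inf
    loss = np.nan
    for epoch in range(1, cfg.epochs + 1):
        loss, grads = _loss_and_gradients_fast(params, XT, YT, cfg.loss_weights)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(epoch)
        for k, g in grads.items():
            if cfg.optimizer == "adam":
                vel[k] = cfg.momentum * vel[k] + (1 - cfg.momentum) * g
                second[k] = b2 * second[k] + (1 - b2) * g * g
                m_hat = vel[k] / (1 - cfg.momentum**epoch)
                v_hat = second[k] / (1 - b2**epoch)
                update = -cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            else:
                vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * g
                update = vel[k]
            setattr(params, k, getattr(params, k) + update)
        if cfg.stop_tolerance > 0 and abs(prev_loss - loss) < cfg.stop_tolerance:
            break
        prev_loss = loss
    params.metadata["final_loss"] = float(loss)
    return params


def replicate_seed(base_seed: int, subject_id: str, replicate_index: int) -> np.random.SeedSequence:
    """Documented derivation: one independent stream per (subject, replicate)."""
    return np.random.SeedSequence(
        [int(base_seed), *map(ord, subject_id), int(replicate_index)]
    )


def make_m_subjects(
    dataset: BehavioralDataset,
    n_replicates: int = 10,
    cfg: TrainingConfig = TrainingConfig(),
    enc: EncodingConfig = DEFAULT_ENCODING,
) -> list[MSubject]:
    """Independently initialized trainings on the same 140 sequences."""
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    sequences = build_training_set(dataset, enc)
    out = []
    for r in range(1, n_replicates + 1):
        seed = int(replicate_seed(cfg.seed, dataset.subject_id, r).generate_state(1)[0] & 0x7FFFFFFF)
        params = train_bptt(
            sequences,
            replace(cfg, seed=seed),
            metadata={"source_subject": dataset.subject_id, "replicate": r},
        )
        out.append(
            MSubject(
                m_subject_id=f"{dataset.subject_id}-M{r:02d}",
                params=params,
                source_subject_id=dataset.subject_id,
                replicate_index=r,
            )
        )
    return out


def _model_curve(params: RNNParams, seqs: list[SensorimotorSequence]) -> YesRateCurve:
    res = run_batch(params, stack_inputs(seqs))
    return yes_rate_curve(
        res.final_soa, [s.trial_type for s in seqs], np.array([s.condition_ms for s in seqs])
    )


def reproduction_check(
    m: MSubject,
    test_set: list[SensorimotorSequence],
    dataset: BehavioralDataset,
    threshold: float = 0.25,
    enc: EncodingConfig = DEFAULT_ENCODING,
) -> MSubject:
    """Fill training/generalization RMSE and the pass flag."""
    subject_curve = dataset.empirical_curve()
    train_curve = _model_curve(m.params, build_training_set(dataset, enc))
    test_curve = _model_curve(m.params, test_set)
    m.training_error = curve_rmse(train_curve, subject_curve)
    m.generalization_error = curve_rmse(test_curve, subject_curve)
    m.reproduction_pass = m.generalization_error <= threshold
    return m


def overlearning_test(m_subjects: list[MSubject]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between training and generalization
    errors across the cohort; non-significance indicates no overlearning."""
    if len(m_subjects) < 2:
        raise ConfigurationError("need at least two checked M-subjects")
    tr = [m.training_error for m in m_subjects]
    ge = [m.generalization_error for m in m_subjects]
    if any(v is None for v in tr + ge):
        raise ConfigurationError("run reproduction_check before overlearning_test")
    return mann_whitney_u(tr, ge)
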