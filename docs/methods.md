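# Methods

`soasim` models explicit sense-of-agency (SoA) judgment in an
agency-attribution task as sensorimotor prediction in a small
continuous-time recurrent neural network (CTRNN), and probes how
temporal delays, state noise and reduced neuronal gain distort that
judgment. This note records the model, the synthetic data it is trained
on, the numerical choices, and what the package's tests do and do not
establish.

## Task and synthetic behavior

In the agency-attribution paradigm an on-screen piece rises steadily; a
beep cues a button press, and the piece jumps either a fixed latency
after the press (*action-linked* trials, latencies 0–1000 ms in 100 ms
steps) or time-locked to the beep itself (*event-prior-to-action*, EPA,
offsets −100/0/+100 ms). The subject reports "yes" (I caused the jump)
or "no". Each of the 14 conditions is repeated 10 times → 140 trials per
subject.

No human data ship with this package. Each synthetic "H-subject" is a
draw from a configurable cohort distribution:

- action-linked yes-probability is a four-parameter logistic in latency
  `p(L) = lower + (upper − lower)·σ(−slope·(L − inflection))`, with
  defaults `inflection ∈ [300, 700]` ms, `slope ∈ [0.010, 0.020]` per
  ms, `upper ∈ [0.90, 1.00]`, `lower ∈ [0.00, 0.08]`. These ranges
  produce near-ceiling yes rates at 0–200 ms and near-floor rates at
  800–1000 ms, the healthy-control signature the model is trained to
  reproduce.
- EPA yes-probability is constant per condition, drawn from
  `[0.10, 0.30]`. Healthy controls rarely claim agency over beep-locked
  jumps, but no published number pins this down; it is configuration,
  not ground truth.
- reaction times are normal with per-subject mean in `[250, 450]` ms
  and SD in `[30, 80]` ms, truncated to ≥ 1 ms by rejection sampling.

Responses are Bernoulli draws from the psychometric probability, so a
subject's *empirical* 10-repetition curve differs from their generating
curve by binomial noise (SE up to ≈ 0.16 per condition at p = 0.5).

Synthetic schizophrenia-pattern reference curves use shifted ranges:
the paranoid-type (PS) group raises the lower asymptote to
`[0.40, 0.65]` and EPA probabilities to `[0.40, 0.70]` (excessive SoA
at long latencies), while the negative-symptom (NS) group lowers the
upper asymptote to `[0.45, 0.70]` (diminished SoA at short latencies).
The default mixed reference is 30 PS + 20 NS exact probability curves.
These are qualitative stand-ins for undeposited patient data; every
number is configurable.

### Seeding

A cohort master seed fixes everything downstream. Subject *i* uses
`SeedSequence([master, i, 0])` for its profile, `([master, i, 1])` for
its trials and `([master, i, 2, r])` for the test set of replicate *r*,
so any subject is regenerable in isolation. Lesion runs draw from a
stream keyed by the lesion seed and the model-subject id, independent
of the training and behavior streams.

## Sequence encoding

Trials are encoded at `dt = 100` ms over `T = 30` steps (3 s): latency
conditions are then exact integer step counts, consistent with a model
that can only delay signals in whole steps. Channels live in
[0.1, 0.9]. The beep is a one-step 0.9 pulse at step 5; the button
press a one-step pulse at `beep + round(rt/dt)`; the position channel
ramps linearly 0.1 → 0.9 with an extra one-step increment (0.2 before
renormalization) at the jump step, then is rescaled so the endpoint is
exactly 0.9. The judgment target starts at the neutral 0.5 and ends at
0.9 (yes) or 0.1 (no).

By default the judgment target stays at 0.5 until the jump step and
ramps linearly only afterwards (`soa_ramp="post_jump"`). Before the
jump, trials of different latency conditions are observationally
identical, so a target that already diverges there demands incompatible
outputs on identical prefixes; in practice that regularizes training
toward hedged outputs and slows convergence badly. The whole-trial
linear ramp remains available (`soa_ramp="full"`).

## Network

Ten context units with full recurrence (self-connections included)
mediate all signal flow between 3 input units (beep, button, position)
and 4 output units (one-step predictions of the three inputs, plus the
SoA judgment). Context potentials are leaky integrators,

    u_i(t) = (1 − 1/τ)·u_i(t−1) + (1/τ)·[Σ_j W_cx[i,j]·x_j(t) + Σ_k W_cc[i,k]·c_k(t−1)]
    c_i(t) = f(u_i(t)),   f(u) = 1/(1 + e^{−a·u})

with τ = 10.0 and gain a = 1.0. Outputs read the context one step
back: `o_i(t) = f(Σ_j W_oc[i,j]·c_j(t−1))`. There are no bias terms
and no direct input→output weights. Before t = 0, context activations
are defined as f(0) = 0.5 and inputs as their 0.1 baseline, making
delayed reads at the sequence start well-defined; u starts at 0.

A trial is judged "yes" iff the final-step SoA output exceeds 0.5, the
neutral midpoint of the 0.1/0.9 coding. The tie (exactly 0.5) counts
as "no".

## Training

All 140 sequences of one subject are fit in batch mode by full-unroll
backpropagation through time on the squared error summed over steps and
channels (mean over sequences). The judgment channel is weighted 3×ばつ so
the single SoA output balances the three sensory channels. Weights
initialize uniformly in ±0.1.

The default optimizer is Adam (learning rate 0.02, β₁ = 0.9,
β₂ = 0.999, 25 000 epochs). Plain gradient descent with momentum is
implemented (`optimizer="momentum"`) but not the default: on this task
it sits on a long plateau (all outputs near the targets' mean) whose
escape time varies by thousands of epochs across seeds, while Adam
leaves it reliably. Gradients are computed twice over: a vectorized
numpy reference implementation, and a numba-compiled fused kernel used
for speed; the test suite holds them to agreement at 1e−10 and the
reference to finite differences at 1e−6.

Ten replicates per subject differ only in their derived initialization
seed ("M-subjects"). After training, each replicate's behavioral
reproduction is scored as the RMSE between the source subject's
empirical 14-condition yes-rate curve and the model's curve on the
training sequences (training error) and on a fresh test set
(generalization error). The default inclusion gate for lesion
experiments is generalization RMSE ≤ 0.25. A tighter 0.15 gate was
considered, but with 100 ms steps and a hard 0.5 judgment threshold the
model's per-condition rates are near-binary while the subject's
empirical rates are graded; RMSE values of 0.15–0.25 are typical for
models whose inflection point and asymptotes are visibly correct, and a
0.15 gate would discard most of them. Cohort-level absence of
overlearning is checked by a two-sided Mann–Whitney U between training
and generalization errors.

### What reproduction does and does not achieve

Trained models place the yes/no transition at the subject's inflection
latency and saturate correctly in both windows. They do *not* reproduce
the graded slope of the psychometric curve condition-by-condition: the
network is deterministic given a sequence, so within one condition only
reaction-time jitter (±1 step after rounding) varies the final output,
and rates at mid-latencies are steeper than the generating logistic.
Reproducing graded rates would need sub-step event timing (excluded by
design: latencies are integer steps) or a stochastic judgment readout
(the threshold rule is deterministic by design). This is the main
known limitation; it bounds the achievable curve-recovery RMSE from
below at roughly 0.1–0.2 depending on the subject's slope and RT
variability.

## Lesions

Lesions apply at test time only and never modify weights:

- **Context delay** (the hypothesis lesion): the recurrent read
  `c_k(t−1)` becomes `c_k(t−1−Δ)` with Δ ∈ {0, 1} drawn independently
  per *receiving* unit per step (all sources of a given unit share the
  delay; the per-receiver reading of the ambiguous index structure is
  recorded here as a choice). P(Δ=1) defaults to 0.5.
- **State noise**: `u_i(t)` is multiplied by `(1 + ξ)`, ξ uniform on
  [−0.01, +0.01] per unit per step ("level" read as amplitude;
  a Gaussian variant with SD = level is available).
- **Output delay**: only the SoA output unit reads `c(t−1−Δ)`, one Δ
  per step.
- **Input delay**: `x_j(t)` becomes `x_j(t−Δ)`, Δ per input unit per
  step.
- **Reduced gain**: a is replaced everywhere (0.99, 0.9 or 0.5).

Observed phenomenology on trained cohorts: the context delay produces
large, replicate-dependent bidirectional changes — some models lose
"yes" responses at short latencies (diminished), others gain them at
long latencies and EPA conditions (excessive), many show both — and its
window-average distribution is the closest of the lesions to the mixed
PS+NS reference by both MSE and KL. The output delay leaves yes-rate
curves essentially identical to healthy ones (it cannot feed back into
the dynamics). The input delay pushes both windows toward chance. The
0.01-amplitude state noise, by contrast, perturbs judgments only near
the decision boundary in this implementation: trained networks are not
chaotic enough for a 1% multiplicative perturbation to randomize
saturated judgments, so fully chance-level behavior under this lesion
is not reproduced. Stronger noise or more excitable training regimes
would close that gap, but the 0.01 level is kept as the study
condition.

## Evaluation

- Yes-rate curves per condition; short window = mean over 0/100/200 ms,
  long window = mean over 800/900/1000 ms.
- Window-average distributions over subjects use 11 equal bins on
  [0, 1]; a value on an interior edge joins the upper bin, 1.0 joins
  the last.
- MSE between distributions is the mean squared per-bin difference; KL
  is KL(reference ‖ model) after adding ε = 1e−6 to every bin and
  renormalizing. Short- and long-window values are averaged to one
  number per comparison.
- Classification: Y = Σ_window 10·(lesioned − healthy)/3 per window.
  The ±2 thresholds act on this 0–10 count-equivalent scale (10
  repetitions per behavioral condition), i.e. a 0.2 mean rate change;
  on raw rates a ±2 threshold would be unreachable. Excessive:
  Y_long > 2; diminished: Y_short < −2; schizophrenia-pattern: both.
- Context-unit analysis: each unit's activation at the step immediately
  before the jump, across action-linked test trials; two-sided
  Mann–Whitney U between yes- and no-judged trials at α = 0.05 and
  Spearman rank correlation against latency at α = 0.01, counted per
  unit with no multiple-testing correction (per-unit α by design).
  Subjects whose test judgments are single-class are skipped for the
  judgment test and logged.

## Problem sizes

Default study scale is 17 subjects ×ばつ 10 replicates with 1400-sequence
test sets. The reproduction script trains a 7-subject ×ばつ 2-replicate
cohort with 1400-sequence test sets; the test suite a 5 ×ばつ 2 cohort
with 700-sequence test sets — large enough that window means, unit
counts and distribution distances are stable, while a full training
sweep stays a desk-scale computation. Replicates failing the
reproduction gate are excluded from lesion statistics, as in the full
design. The `soasim` CLI's `--profile smoke` preset
(3 ×ばつ 2, 280-sequence test sets) is for quick end-to-end checks.

## Known limitations

- Graded psychometric slopes are not recovered condition-by-condition
  (see above); curve recovery is assessed at the inflection/asymptote
  level.
- The noise lesion at amplitude 0.01 does not randomize judgments in
  this implementation.
- EPA conditions, 30 of 140 training trials, are the least reliably
  fit; occasional replicates answer "yes" on the pre-beep EPA condition
  their source subject mostly declined.
- The model is open-loop: predictions are never fed back as inputs, and
  there is no within-experiment learning.
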