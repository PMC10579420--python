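"""Task-level constants of the agency-attribution (Keio-style) paradigm.

The task has two trial families: *action-linked* trials, in which the
on-screen piece jumps some latency after the subject's button press, and
*event-prior-to-action* (EPA) trials, in which the jump is time-locked to
the beep instead. Each of the 11 + 3 conditions is repeated 10 times,
giving 140 trials per subject.
"""

ACTION_LINKED = "action_linked"
EPA = "epa"

#: Action-linked jumping latencies in ms (11 conditions).
ACTION_LATENCIES_MS: tuple[int, ...] = tuple(range(0, 1001, 100))

#: EPA jump offsets relative to the beep, in ms (3 conditions).
EPA_OFFSETS_MS: tuple[int, ...] = (-100, 0, 100)

#: Repetitions of every condition within a subject's session.
N_REPEATS_PER_CONDITION = 10

#: Trials per subject: 11 * 10 action-linked + 3 * 10 EPA.
N_TRIALS_PER_SUBJECT = (
    len(ACTION_LATENCIES_MS) + len(EPA_OFFSETS_MS)
) * N_REPEATS_PER_CONDITION

#: Latency windows (ms) used for the short/long window summaries.
SHORT_WINDOW_MS: tuple[int, ...] = (0, 100, 200)
LONG_WINDOW_MS: tuple[int, ...] = (800, 900, 1000)

#: All 14 conditions as (trial_type, condition_ms) pairs, in canonical order.
ALL_CONDITIONS: tuple[tuple[str, int], ...] = tuple(
    [(ACTION_LINKED, ms) for ms in ACTION_LATENCIES_MS]
    + [(EPA, ms) for ms in EPA_OFFSETS_MS]
)
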