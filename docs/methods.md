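# Methods

## The task

The Spatial Delayed Recognition Span Task (SDRST) measures visuospatial
working memory as a *span*. A stimulus appears in one of the grid's
locations (16 by default) and the participant touches it. It then reappears
at the same location together with a new stimulus in a different location;
the participant must touch the stimulus in the *novel* location. The array
grows by one item per correct touch, up to a ceiling of `max_items`
(default 8). The first mistake ends the trial; touching all `max_items`
novel locations ends it at ceiling. The trial's span is the number of
consecutive correct touches from the start — the forced first touch (a
single stimulus on screen cannot be missed) counts, so span ∈ [1,
max_items]. Performance is the mean span over trials, aggregated per
stimulus category × condition (unique: one image repeated within a trial;
varied: all images distinct) × emotional valence.

This package is a headless re-implementation: stimuli are opaque
identifiers with category/valence/size metadata, locations are abstract
grid-cell indices, and "touches" are events in a log. Nothing is rendered
and no audio is played; feedback is an event with a kind
(`correct_tone` / `wrong_tone` / `reward` / `none`) determined by the
configured feedback mode.

## Parameters that matter

| parameter | unit | default | role |
|---|---|---|---|
| `grid` | — | 4×4 (16 cells) | locations available for placement; the 4×4 evenly spaced layout is the simplest symmetric arrangement of 16 locations (the studies specify only the count) |
| `max_items` | items | 8 | span ceiling; must not exceed the number of grid cells |
| `interval_time_ms` | ms | 1000 (presets: 5000/3000/1000) | pause between a response and the next display; the only timing parameter that enters synthetic event timestamps |
| `exposure_time_ms`, `delay_time_ms` | ms | 1000 / 0 | stored and echoed in logs verbatim; the engine attaches no behaviour to them because the task description lists them without defining their role, and timestamps here are event-driven rather than scheduled |
| `trials_per_valence` | trials | per preset | trial counts per valence; when omitted, trials are split as evenly as possible across the valences present in the stimulus set (enum order, remainder to the earliest) |
| `rng_seed` | — | 0 | root seed; trial *i*'s plan is drawn from a generator seeded by `(rng_seed, i)`, so it is invariant to how many trials precede it, and the valence order comes from a separate stream `(rng_seed, 2^32)` |

Trial order interleaves valences via a deterministic shuffle from the
config seed; the studies do not state their ordering or counterbalancing.

## Presets

`study_a` / `study_b` / `study_c` encode the three validation studies:
16 locations and an 8-item ceiling throughout; inter-stimulus intervals of
5 s, 3 s and 1 s respectively; 16 trials per valence (IAPS scenes +
geometric figures) for a and c, 10 per valence (faces + geometric, 40
trials total, auditory feedback) for b. Stimulus ids are abstract
placeholders — the published IAPS/face image sets are licensed materials
and are not shipped — with 8 ids per valence so the varied condition is
runnable. Presets default to the unique condition; switch with
`config.with_updates(condition="varied")`.

## Simulated participants

The **chance agent** touches a uniformly random visible stimulus. At step
*k* there are *k* stimuli and success probability 1/*k*, so
P(span ≥ j) = 1/j! and

    E[span] = Σ_{k=1}^{max_items} 1/k!   (≈ 1.71828 at max_items = 8),

the chance level against which any performance is judged.

The **capacity agent** is a parametric stand-in for a limited visuospatial
store: it retains the `m` most recent *true* novel locations (FIFO
eviction — a recency assumption) and, unless it lapses with probability
`eps` (uniform over all visible), touches a uniformly random visible
location *not* in memory. Memory is updated with the true target after
every response regardless of the choice made, because the task's corrective
structure (advance vs. trial end) reveals the answer; this also keeps the
model analytically tractable. Because memory content at step *k* is then
deterministic given the trial reached it — the last min(m, k−1) targets,
all distinct old locations — the per-step success probability is exact:

    p_k = eps/k + (1 − eps)/(k − min(m, k − 1)),

and E[span] = Σ_j Π_{k≤j} p_k (`expected_capacity_span`). Limits:
(m=0, eps=0) is distributionally the chance agent; (m ≥ max_items−1,
eps=0) is a perfect responder. Mean span is monotonically non-decreasing
in `m` and non-increasing in `eps`.

Synthetic response latencies are lognormal, moment-matched to a configured
mean/sd (defaults 800/250 ms, ordinary touch-response magnitudes) and
floored at 1 ms so latencies are strictly positive. They feed the
`mean_rt_ms` summaries; they carry no behavioural consequence.

## Scoring conventions

- Span per trial is recomputed from the response stream (first-error scan);
  the engine's logged span must agree.
- Cell SDs use the sample estimator (n−1); a one-trial cell reports NaN and
  prints as "-". The published tables print "M (SD)" without naming the
  estimator; n−1 is the convention assumed.
- Response time is anchored to the display event: latency = response
  timestamp − timestamp of the display it answers.
- Trials containing no valid response (only invalid touches) are excluded
  from span statistics and counted separately; a touch outside any visible
  stimulus is logged (`invalid_touch`) but never counts as a response,
  as a touchscreen ignores background contact.
- Summaries pool trials within each (category, condition, valence) cell of
  a session; the overall mean therefore equals the trial-count-weighted
  mean of cell means.

## Cohorts

A cohort draws per-subject parameters — `m` from an integer-rounded normal
clipped at 0, `eps` from a normal truncated to [0, 1] (inverse-CDF
sampling, so draws are deterministic given the seed) — and runs one session
per subject. Group statistics weight subjects equally (mean of subject
means), the usual convention for behavioural group tables; group contrasts
are subject-level bootstraps (resampling subjects with replacement within
each group, percentile 95% CI). Condition and valence effects are *not*
built into the agent; the optional `varied_m_bonus` adds a fixed capacity
increment in the varied condition purely to illustrate the direction of the
published condition effect and makes no mechanistic claim.

## What the simulations do and do not show

The generator emulates the task's *structure* — constrained-random
placement, growing arrays, termination on first error, per-valence trial
counts — with agents whose only psychology is a capacity and a lapse rate.
It does not emulate human valence sensitivity, stimulus-type effects,
fatigue, learning across trials, or spatial response biases, so passing
tests certify the engine and scoring pipeline, not any claim about human
data; published group means and F statistics are measurements of people and
are out of scope. Group-table output reproduces the published table's
*shape* (groups × stimulus type / condition / valence margins) from
simulated cohorts.

## Numerical and degenerate-input choices

- All randomness flows through named `numpy` `SeedSequence` streams; two
  runs with the same config seed and agent seed produce byte-identical
  JSONL logs (compact JSON, sorted keys) and CSV summaries.
- Timestamps are non-negative integers and must be monotone; a response
  timestamped before the last event is rejected.
- `expected_random_span(1)` = 1 (a single forced touch); `max_items < 1`
  is an error. An empty display is an error for every choice rule.
- Monte-Carlo checks in the test suite compare simulated means to exact
  values within 3 standard errors, with simulation sizes (10^4–10^5
  trials) chosen so that the standard error is far below the effects being
  checked.
- Cohort `m` rounds to the nearest integer before clipping; `eps_sd = 0`
  degenerates to the clipped mean.

## Known limitations

- No real-time scheduling: exposure and delay times are metadata, and
  event timestamps are synthetic (agent latencies) or supplied by a
  replayed log.
- The capacity agent's FIFO memory is one of many plausible forgetting
  rules; nothing here arbitrates between recency and other eviction
  policies.
- Per-session cells pool trials; analyses that first average within
  participants and then across valence blocks should use the cohort layer.
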