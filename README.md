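# sdrst

A headless, fully configurable engine for the **Spatial Delayed Recognition
Span Task (SDRST)**, a touchscreen measure of visuospatial working memory
used with young adults, older adults, Alzheimer's patients and non-human
primates. The package is for researchers who want to run, simulate, log,
replay and score the paradigm without a tablet: trial generation, the
event-driven session state machine, span scoring, simulated participants,
and cohort-level group tables with bootstrap contrasts.

## The task and its measure

A stimulus appears in one of 16 grid locations and the participant touches
it; it reappears in the same place together with a new stimulus in a
different location, and the participant must touch the stimulus in the
**novel location**. The array grows by one item per correct touch up to a
ceiling of 8; the first mistake ends the trial. The performance measure is
the **span**: the number of consecutive correct touches in a trial,

    span ∈ [1, max_items],

averaged over trials and broken down by stimulus type (geometric, IAPS
scene, face), condition (**unique**: one image repeated within a trial;
**varied**: all images distinct) and emotional valence
(negative/positive/neutral).

A participant touching uniformly at random succeeds at step *k* with
probability 1/*k*, giving the chance level in closed form:

    E[span | chance] = Σ_{k=1}^{max_items} 1/k!  ≈ 1.71828  (max_items = 8).

Simulated participants are parameterised by a working-memory capacity *m*
(most recent old locations retained) and a lapse rate ε; their exact mean
span is `Σ_j Π_{k≤j} p_k` with `p_k = ε/k + (1−ε)/(k − min(m, k−1))`.
See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate one session of the face study (40 trials, 10 per valence, 3 s
inter-stimulus interval, auditory feedback) with a capacity-4 agent that
lapses 5% of the time, then score the log:

```sh
sdrst preset study_b --out b.json
sdrst simulate --config b.json --agent capacity --agent-param m=4 \
    --agent-param eps=0.05 --seed 3 --out log.jsonl
sdrst score --log log.jsonl --out summary.csv
```

```
Session: log  (span ceiling 8)
Overall: 5.25 (1.13)  over 40 trials
        face | unique | negative : 5.50 (1.35)  n=10
        face | unique |  neutral : 5.20 (0.92)  n=10
        face | unique | positive : 5.10 (1.20)  n=10
   geometric | unique |     none : 5.20 (1.14)  n=10
```

Each row is one stimulus-category × condition × valence cell with mean
(sample SD) of trial spans and its trial count. The overall mean 5.25 sits
between the exact expectation for this agent
(`expected_capacity_span(4, 0.05, 8)` ≈ 5.29) and the chance level 1.72 —
the agent remembers four old locations, so it is far above chance but
below the ceiling of 8. The session log is JSON Lines (one display /
response / feedback / trial_end / session_end event per line, monotone
millisecond timestamps) and is byte-reproducible from the two seeds.

Simulate two groups and contrast them:

```sh
cat > cohorts.json <<'EOF'
[{"group_label": "hi", "n_subjects": 4, "m_mean": 6, "preset": "study_b"},
 {"group_label": "lo", "n_subjects": 4, "m_mean": 2, "preset": "study_b"}]
EOF
sdrst cohort --spec cohorts.json --boot 500 --seed 2
```

```
   Type of stimuli              Task condition Emotional valence
         geometric         face         Unique          Negative     Positive      Neutral
hi     7.50 (0.14)  7.53 (0.13)    7.52 (0.12)       7.45 (0.17)  7.62 (0.17)  7.50 (0.14)
lo     3.85 (0.24)  3.61 (0.19)    3.67 (0.10)       3.45 (0.17)  3.70 (0.34)  3.67 (0.34)
hi - lo: +3.850  [95% CI +3.719, +3.969]
```

Rows are groups, columns the marginal cells of the standard group-table
layout ("M (SD)" across subjects, "-" for cells a group never ran); the
last line is the subject-level bootstrap contrast of overall mean span
with its percentile 95% CI. The same operations are available as library
functions (`sdrst.run_with_agent`, `sdrst.summarize_session`,
`sdrst.simulate_cohort`, ...).

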