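# cogavoid

A headless, desk-scale toolkit for a room-scale VR avoidance-conditioning
paradigm. In the task it models, a participant shares an 8 m × 8 m virtual
room with a pedestal on which one of two conditioned stimuli (CS+ or CS−)
appears for 9 s. On 75 % of CS+ trials an aversive 1-s sound (the US) plays
from the pedestal 8 s after CS onset, co-terminating with the CS. The sound's
level decays linearly with distance — 80 dB at the source, 25 % per meter,
inaudible beyond 4 m — so simply walking away is an effective, uninstructed
avoidance response. Sessions progress through Pavlovian acquisition (seated),
free avoidance learning, an incidental coin-search transfer task, extinction
with an instruction to approach, and (in some designs) extinction recall and
reinstatement by an unsignalled US.

The package is aimed at researchers who want to prototype task designs,
analysis pipelines and power considerations for this class of paradigm
without VR hardware. It provides:

- **`task_model`** — declarative experiment specs (room, US field, stimuli,
  phases), schedule generation with exact partial reinforcement and
  participant-parity counterbalancing, JSON/CSV config I/O, and the five
  packaged experiment templates (`exp1` … `exp5`).
- **`sim_engine`** — simulated participants: per-condition CS–US
  associations updated by the delta rule `V ← V + α(λ − V)` with a
  perceived-US outcome (a delivered US counts only if the agent is inside
  the audible radius, unless the speaker-vibration cue is on), and a
  distance-regulating movement policy that walks away from a feared CS,
  approaches under instruction, and drifts otherwise.
- **`uxf_io`** — UXF-style session logs: one `trial_results.csv` row per
  trial, one movement CSV per tracker per trial (Unity left-handed y-up
  frame), event markers, and handedness conversion.
- **`kinematics`** — the seven trial-level statistics over the CS-onset →
  US-onset window: mean/max/min distance to the CS, path length, maximum
  speed, mean absolute head angle to the CS, and the reaction time of the
  first ≥ 0.7 m head displacement.
- **`stats`** — per-participant condition aggregation; paired Cohen's
  d_z = mean(ΔCS) / SD(ΔCS) and Hedges' g = d·J with J = 1 − 3/(4·df − 1)
  and a noncentral-t 95 % CI; the mixed models
  `DV ~ CS*trial_num + (1|ppid)` and `DV ~ CS*phase + trial_num + (1|ppid)`;
  and sensitivity power analysis for one-sided paired t tests.
- **`cogavoid`** (CLI) — `simulate`, `analyze`, `fixtures`, `report`.

## Worked example

```bash
cogavoid simulate --template exp3 --n 12 --seed 7 --out scratch/exp3
cogavoid analyze scratch/exp3/P0* --out scratch/exp3_analysis
```

The analyze step prints the per-phase paired effect sizes it writes to
`effect_sizes.csv`; the first lines for the avoidance phase look like:

```
                phase             dv  cohens_d  hedges_g  ci_low  ci_high  n_pairs
   avoidance_learning    mean_dist_m     5.331     4.959   2.846    7.062       12
   avoidance_learning     max_dist_m     5.333     4.961   2.847    7.063       12
   avoidance_learning     min_dist_m     1.794     1.669   0.789    2.521       12
```

Simulated avoiders walk from the 1-m starting point to about 4 m on CS+
trials and drift near 1 m on CS− trials, so the CS+/CS− contrast in mean
distance is positive and — because the agents are far less variable than
humans — the standardized effect is much larger than the 0.2–0.9 range
reported for real participants; the *direction* and its extinction under the
approach instruction are the point. `model_results.csv` holds the
mixed-model fixed effects, e.g. a negative `cs:phase_code` interaction for
the avoidance → extinction comparison (the extinction criterion).

The same pipeline is available as library calls (`run_cohort`,
`summarize_session`, `paired_effect_size`, `fit_cross_phase_model`, …); see
the module docstrings and `docs/methods.md`.

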