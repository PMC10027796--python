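# trialvr

A headless, hardware-free Python framework for **trial-based behavioral
experiments in virtual reality**, aimed at researchers who study reaching,
eye movements, and other continuous behavior in head-mounted-display setups
— and at anyone who wants to prototype, simulate, or analyze such
experiments without a VR rig attached.

The package provides, as plain library code:

* **Experimental design management** — full-factorial design generation,
  CSV import of trial tables, global or within-block randomization, a
  pre/main/post task run loop, and single-file JSON plus per-trial CSV
  serialization of entire sessions (`trialvr.design`, `trialvr.session_io`).
* **Frame-locked continuous recording** — one sample per simulated display
  refresh (90 Hz default) of every registered tracked node, with automatic
  conversion of tracker-frame gaze rays to world space and per-frame
  raycasting against the scene to log the fixated object and 3D gaze point
  (`trialvr.recorder`, `trialvr.geometry`).
* **Eye-tracker validation metrics** — a five-target cross layout (central
  plus ±5° targets) and per-target gaze **accuracy** (mean angular error),
  **precision SD**, and **RMSE** (`trialvr.validation`).
* **Seeded device simulators** — an HMD, an eye tracker with configurable
  angular bias and noise, and a hand controller executing minimum-jerk
  reaches, including scripted participant "mistakes" such as starting
  before the go cue or glancing at the target (`trialvr.simulate`).
* **A complete example task** — the pro-/anti-reach paradigm: 2 (target
  side) × 2 (pro/anti cue) × 2 (controller feedback) × 10 repetitions = 80
  trials, with a gaze-contingent fixation phase and a depth-threshold
  trial end (`trialvr.proanti`).
* **A kinematics analysis pipeline** — velocity-criterion movement onset,
  movement latency and duration, horizontal endpoint error, correct-
  hemifield rate, ±3 SD outlier removal, per-condition aggregation, and
  gaze-on-plane trace extraction (`trialvr.analysis`).

## The measures at the core

For a trial with go cue at time $t_{go}$, the controller velocity is
computed by backward differences of the recorded positions,
$v_i = (p_i - p_{i-1}) / (t_i - t_{i-1})$, and movement onset $t_{on}$ is
the first sample with $v_z$ above a threshold (default 0.05 m/s). Then

* movement latency $= t_{on} - t_{go}$ (negative if the participant
  started early),
* movement duration $= t_{cross} - t_{on}$, where $t_{cross}$ is the first
  frame at which the controller depth reaches the 45 cm threshold,
* horizontal endpoint error $= |x(t_{cross}) - x_{ref}|$, computed against
  both the visual target ($x_{ref} = x_{target}$, the default) and the
  instructed goal ($x_{ref} = x_{goal} = \pm x_{target}$).

Gaze quality over $n$ fixation samples with angular errors $\theta_i$
(angle between the gaze direction and the true origin→target direction):
accuracy $= \bar\theta$, precision SD $= s_\theta$ (ddof = 1), and
RMSE $= \sqrt{\tfrac1n\sum\theta_i^2}$, which satisfy
$\mathrm{RMSE}^2 = \bar\theta^2 + \tfrac{n-1}{n}s_\theta^2$.

Simulated reaches follow the minimum-jerk profile with displacement
fraction $10\tau^3 - 15\tau^4 + 6\tau^5$ and peak speed
$1.875\,D/T$.

## Worked example

```python
from trialvr import (run_proanti_session, session_measures, filter_outliers,
                     aggregate_by_condition, summarize_validation)
from trialvr.proanti import TaskConfig
from trialvr.simulate import ParticipantProfile

session = run_proanti_session(TaskConfig(), ParticipantProfile(mode="compliant"),
                              seed=42, participant="P01")
print("trials done:", sum(t.status == "done" for t in session.trials))
summary = summarize_validation(session.validations[0])
print(f"validation: accuracy {summary['mean_accuracy_deg']:.3f} deg, "
      f"precision SD {summary['mean_sd_deg']:.3f} deg, RMSE {summary['mean_rmse_deg']:.3f} deg")
measures = filter_outliers(session_measures(session))
agg = aggregate_by_condition(measures)
print(agg[["target_side", "cue", "latency_mean", "duration_mean",
           "error_vs_target_mean", "correct_rate"]].round(3).to_string(index=False))
```

prints

```
trials done: 80
validation: accuracy 0.564 deg, precision SD 0.265 deg, RMSE 0.623 deg
target_side  cue  latency_mean  duration_mean  error_vs_target_mean  correct_rate
       left anti         0.468          0.308                   0.6           1.0
       left  pro         0.484          0.329                   0.0           1.0
      right anti         0.502          0.327                   0.6           1.0
      right  pro         0.498          0.308                   0.0           1.0
```

All 80 trials complete; the simulated eye tracker's per-participant bias
(drawn in 0.2–0.7°) plus 0.3°/axis noise yields ~0.56° validation accuracy.
Mean latencies sit near the simulated 0.45 s with ~0.3 s movement
durations, every reach lands in the correct hemifield, and anti-reach
trials show the expected 0.60 m horizontal error *relative to the visual
target* (twice the 30 cm eccentricity) while being exactly on goal —
`error_vs_goal_mean` is 0 in the same table.

## Command line

```bash
trialvr simulate -n 5 --seed 1 --out data/        # 5 sessions incl. scripted mistakes
trialvr analyze --in data/ --out analysis/        # measures.csv, aggregates.csv, figures
trialvr validate-report --in data/P01_session.json
trialvr roundtrip-check --in data/P01_session.json
```

`simulate` writes, per participant, the session JSON, one-row-per-trial
CSV, one-row-per-frame sample CSV, and a validation report CSV. The
default five-participant cohort includes one early-starter and one
participant who glances at the target, so the downstream analysis exhibits
negative latencies and horizontal gaze shifts.

## Layout

```
src/trialvr/      design, geometry, recorder, validation, simulate,
                  proanti, analysis, session_io, cli
tests/            pytest suite (unit, property, and acceptance tests)
docs/methods.md   models, conventions, parameter choices, limitations
```

Rendering, real device SDKs, and statistical hypothesis testing are
deliberately out of scope; see `docs/methods.md`.
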