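# Methods and design notes

This note documents the models, conventions, and parameter choices
behind `trialvr`, what the synthetic devices do and do not emulate, and
the known limitations of the approach.

## Coordinate conventions

All 3D quantities use a right-handed frame with X right, Y up, Z forward
(away from the participant), in meters. Lateral stimulus offsets are
signed X; "depth" is Z. Orientations are stored as unit quaternions and
exported as yaw(Y)–pitch(X)–roll(Z) Euler angles in degrees. VR engines
disagree on handedness; one choice had to be fixed and documented. All
derived measures used by the analysis (angles, distances, durations) are
invariant to this choice, but raw-coordinate parity with any particular
engine is not a goal.

## Session model and serialization

A session owns an ordered list of trials; each trial carries `params`
(independent variables), `results` (writable only once the trial is
running), an event log, and optionally the per-frame samples recorded
during it. Trials have a creation index (0-based, stable under
randomization) and a presentation number (1-based, assigned at run
time); both appear in outputs because randomization makes them differ.

CSV conventions: comma separator, `.` decimal, UTF-8, mandatory header
row. Type inference on import tries int, then float, then the literals
`true`/`false`, else text; empty cells are null. This rule is
deterministic so that save → load round trips reproduce values; its one
known lossy case is a text value that *looks* numeric (e.g. the string
`"5"`), which reloads as a number. Nested parameter groups flatten to
`parent.child` column names one level deep.

Session JSON (`trialvr-session/1`) is a single self-contained document
holding metadata, config, validation results, and all trials with
params, results, events, and samples. Floats are emitted with full
`repr` precision, so `load(save(x))` is the identity on every persisted
field. Invalid/missing data are `null` in JSON, empty cells in CSV, and
`None`/validity flags in memory — lossless and unambiguous in each
format.

During a run, trials execute strictly in list order through optional
pre-task, main task, and optional post-task callables. An uncaught task
exception marks the trial `error`; the run then aborts (default) or
continues, governed by a config flag. The run loop was kept as plain
callables receiving the current trial — frame control lives in the
explicit simulated clock captured by the task closures, which keeps the
loop engine-agnostic and trivially testable.

## Frame-locked recording and gaze raycasting

The recorder polls every registered source exactly once per simulated
display refresh (default 90 Hz; `time = frame / rate`). Gaze is a single
combined ("cyclopean") ray originating between the eyes — per-eye
channels are out of scope. The tracker-frame ray is transformed by the
head pose (origin as a point, direction as a direction), then
intersected with every raycast-enabled scene primitive; the closest hit
(smallest non-negative ray parameter, ties by registration order) gives
the fixated-object id and 3D gaze point. Visibility and pickability are
independent flags, which is what lets the task keep an *invisible*
gaze-recording plane as the only pickable object during reaches.

Frame-locked sampling is a deliberate fidelity trade-off: real trackers
can sample faster than the display refresh, so hardware data recorded
this way is temporally quantized. In this headless artifact the
simulated devices are themselves only defined at frame times, so no
additional error is introduced — but conclusions about timing precision
transfer to real hardware only up to that quantization.

Numerical choices: intersection tolerance 1e-9 m; a vanishing sphere
discriminant (grazing ray) counts as a hit; bounded-plane extent checks
are inclusive within tolerance. Source failures mark the affected fields
invalid for that frame and never abort a recording.

## Eye-tracker validation

Targets are placed on a sphere of the requested depth around the
cyclopean origin, at exact angular offsets (a pure horizontal offset of
e° is exactly e° of eccentricity, likewise vertical). The default layout
is the five-target cross: center plus ±5° horizontal and vertical, at
0.5 m depth.

The angular error of each sample is the scalar angle between the
measured gaze direction and the true origin→target direction — not a 2D
screen-plane decomposition. Per target: accuracy = mean error,
precision SD = sample SD (ddof = 1), RMSE = root mean square (population
n). With these conventions `rmse² = accuracy² + (n−1)/n · sd²` holds by
construction and is asserted in the tests. RMSE is error-vs-target;
sample-to-sample RMS dispersion would be a different (unimplemented)
metric.

The fixation window is 1.0 s per target with the first 0.2 s discarded
as saccade settling (both configurable); at 90 Hz that keeps 72 samples
per target. A target with zero valid samples is flagged and excluded
from averages. Running a tracker's own built-in calibration is out of
scope (hardware-internal).

## Synthetic devices

The simulators emulate a 90 Hz HMD session of the example task:

* **Head**: static pose at eye height (default 1.60 m — a typical
  standing eye height) facing +Z, with optional Gaussian positional
  jitter (default 0).
* **Gaze**: ray toward the current fixation point, rotated by a constant
  per-participant bias and per-frame independent Gaussian noise
  (default 0.3°/axis). The bias magnitude defaults to a per-participant
  uniform draw in [0.2°, 0.7°], the accuracy range typical of consumer
  VR eye trackers; its direction is random. Angular perturbations are
  yaw/pitch rotations, so for directions near straight-ahead the error
  magnitude is √(h²+v²) to second order; with isotropic noise σ the
  per-sample error is Rayleigh(σ) (mean σ√(π/2)), and with bias δ it is
  Rice(δ, σ) — both used as closed-form oracles in the tests.
* **Controller**: holds at a start position (default (0, 1.30, 0.05) m,
  a relaxed right hand), then executes a scheduled reach. Depth follows
  a minimum-jerk profile (displacement fraction 10τ³−15τ⁴+6τ⁵, peak
  speed 1.875·D/T) over the full movement duration, while lateral (x, y)
  displacement completes over the first 70% of it. Human reaches to
  lateral targets are not straight lines; this two-timescale profile is
  the package's trajectory model and has the useful property that the
  hand is already at the goal's lateral position when it crosses the
  trial-ending depth threshold (which sits at ~75% of the depth path),
  so noiseless endpoint errors are exactly zero.
* **Per-trial draws**: onset latency ~ N(0.45 s, 0.08 s) truncated at 0
  and duration ~ N(0.5 s, 0.1 s) floored at 0.15 s for compliant
  behavior; the `early_start` profile draws latency ~ N(−0.2 s, 0.05 s)
  (movement begins before the go cue), and `gaze_to_target` re-fixates
  the target at its onset instead of holding central fixation. These
  two modes reproduce the classic participant mistakes that kinematic
  pipelines must survive.

All randomness flows from numpy `Generator`s seeded at construction:
identical seeds give byte-identical sample streams. Noise is independent
per axis and frame — no temporal autocorrelation, no saccade dynamics,
no main-sequence behavior, and no biomechanical arm model. Passing tests
therefore demonstrate correctness of the *pipeline* (geometry, timing,
statistics, parameter recovery), not realism of eye or arm physiology;
real data adds drift, blinks, tracker dropouts, and curved reaches that
the simulators intentionally omit.

## The pro-/anti-reach task

Factors: target side (left/right, ±30 cm from the body midline), cue
(pro/anti), controller feedback (visible/hidden); 10 repetitions → 80
trials, shuffled. Derived params: `target_x = ±0.30`, `goal_x =
target_x` (pro) or `−target_x` (anti). Stimuli (5 cm fixation sphere and
same-size target cube) appear at eye height and 0.5 m depth; the sphere
recolors blue (pro) or red (anti) as the direction cue; the target is
shown for 1.0 s; the disappearance of both is the go cue; the trial ends
at the first frame the controller depth reaches 0.45 m.

Open points the task had to fix operationally:

* *Fixation acquisition*: the gaze ray must hit the fixation sphere on
  every frame of a sliding 1.0 s window; any miss resets the window; a
  configurable timeout (10 s) raises a trial error. No blink-tolerance
  rule is implemented — a documented choice, not a claim about the
  original behavior.
* *Raycast bookkeeping*: the sphere is pickable only during the
  acquisition phase (the hit test needs it); from cue onset on, the
  invisible fronto-parallel plane at target depth is the only pickable
  object, so logged gaze points always lie in the target plane.
* *Threshold crossing*: evaluated on the raw depth coordinate at frame
  boundaries, no interpolation — the crossing frame ends the trial, like
  a per-frame proximity sensor.
* *Body midline*: x = 0, defined by the head start position.
* *Inter-trial instruction screen*: reduced to a logged
  `trial_start_confirmed` event (a headless artifact has no UI).
* *Controller visibility* (the feedback factor) is set at trial start
  and recorded in every sample's state flags.

## Analysis pipeline

Velocity is a backward difference assigned to the later sample, with no
smoothing by default (none is needed for frame-locked simulated data; a
moving-average window can be applied by the caller before onset
detection if real data demands it). Movement onset is the first sample
with +Z velocity above the threshold (default 0.05 m/s, configurable and
logged in the analysis run metadata), searched over the whole trial so
that early starts yield negative latencies. Duration runs from onset to
the threshold-crossing event.

Horizontal endpoint error is reported twice: `error_vs_target` (against
the visual target — on anti trials a correct reach is then ~0.60 m
"wrong", i.e. twice the eccentricity) and `error_vs_goal` (against the
mirrored goal). Both are kept because the target-referenced definition
is the literal one while the goal-referenced one is the behaviorally
meaningful one for anti reaches; the target-referenced value is the
default column in figures.

Outlier removal flags trials with latency or duration outside
mean ± 3 SD, computed per participant (not pooled across participants),
pooled across conditions, over defined values only, in a single pass
(no re-computation after exclusion — so the filter is idempotent by
convention). Aggregation per target-side × cue cell: per-participant DV
means, then the across-participant mean and standard error (SD of
participant means / √N); the correct-response rate is the proportion of
non-outlier trials whose crossing X falls in the goal hemifield. Empty
cells are reported as missing, never as zero.

Parameter recovery has a subtlety worth recording: the velocity
criterion fires not at the true movement onset but after the analytic
minimum-jerk rise lag (solve 30τ²(1−τ)²·D/T = threshold), and the
backward difference is an interval average, centering the estimate half
a frame late. The recovery tests compare against these closed forms and
require agreement within one frame (11.1 ms at 90 Hz) across a full
noiseless 80-trial session.

## Problem sizes

The test suite and acceptance script run entirely on simulated data
generated at run time: single trials and 8-trial (one repetition)
sessions for timing and serialization checks, full 80-trial sessions for
the end-to-end recovery and session-level invariants, and 900-sample
windows for the Monte-Carlo validation statistics. A full simulated
session is ~20,000 frames.

## Known limitations

* No rendering, no real device SDKs; device adapters are the seam where
  hardware would plug in.
* Single combined gaze ray; no per-eye data, no saccade/fixation event
  detection.
* Frame-locked acquisition only; no background high-rate sampling.
* Scene primitives are spheres, oriented boxes, and bounded planes; no
  arbitrary meshes, no transform hierarchies deeper than one parent.
* No statistical inference — the pipeline stops at condition means,
  standard errors, and rates.
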