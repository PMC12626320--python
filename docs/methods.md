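# Methods

This note documents the models, parameter choices, and numerical decisions
behind `wormtrack`, and what the synthetic validation does and does not
establish about real recordings.

## Geometry

Boxes live in a continuous image coordinate frame: origin top-left, x
rightward, y downward; a box is the closed real rectangle
[cx − w/2, cx + w/2] × [cy − h/2, cy + h/2]. The canonical in-memory form is
center-width-height; corner and normalized forms exist only at file
boundaries. Working in continuous coordinates avoids off-by-one area
disputes that plague integer pixel-grid conventions, and IoU is the exact
rectangle intersection over union.

## Tracker

**State model.** Each identity carries an 8-dimensional Gaussian state
(cx, cy, r, h, and their per-frame velocities), where r = w/h. The motion
model is constant velocity with Δt = 1 frame. Process and measurement noise
follow the height-scaled convention standard in tracking-by-detection:
position standard deviations of h/20 and velocity standard deviations of
h/160, with the aspect-ratio component held nearly constant (1e-2 / 1e-5).
Scaling by box height makes the filter equally tuned for larval and adult
worms in the same field of view. Both scales are exposed as config
multipliers.

**Association.** Per frame, detections split at two confidence thresholds:

| parameter | default | meaning |
|---|---|---|
| `tau_high` | 0.6 | high-confidence group boundary |
| `tau_low` | 0.1 | floor below which detections are dropped |
| `tau_init` | 0.7 | minimum score to found a new identity |
| `iou_gate_stage1` | 0.2 | min IoU for high-box ↔ active-track and reactivation matches |
| `iou_gate_stage2` | 0.5 | min IoU for low-box ↔ surviving-track matches |
| `max_lost_frames` | 30 | frames a lost identity is retained |

Stage 1 Hungarian-matches high-confidence boxes to active tracks on
1 − IoU cost; stage 2 matches the *remaining* active tracks to
low-confidence boxes — the retention step that preserves identities when
occlusion or partial overlap depresses detector confidence; leftover
high-confidence boxes are then matched to lost tracks (reactivation) before
founding new identities. Unmatched low-confidence boxes are discarded;
unmatched active tracks become lost; lost tracks age out after
`max_lost_frames`. The second-stage gate is stricter than the first because
low-score boxes carry no appearance evidence: only a strong spatial match
justifies consuming one.

These six thresholds have no single published source of truth for worm
assays; the defaults are the values in common use for the two-stage
association strategy and every one is config-exposed and echoed into run
artifacts.

**Determinism.** `scipy.optimize.linear_sum_assignment` is deterministic,
and equal-cost ties resolve to its lowest-index preference; this tie-break
is pinned by test so that identical inputs always produce bit-identical
track files. Track ids increment monotonically and are never recycled.

## Behavior estimators

All computation is in pixels and seconds; `pixel_scale` (µm/px), when set,
converts reported summary speeds.

**Speed.** Instantaneous speed is the centroid displacement magnitude per
inter-frame interval (direction deliberately ignored). Average speed is
total path length over total time, which equals the duration-weighted mean
of instantaneous speeds. The per-worm headline number is the arithmetic mean
of 1-second-bin average speeds, bins aligned to the first sample; a trailing
partial bin shorter than 0.5 s is dropped as too noisy to average. Speed
series for plotting pass through a centered moving average (default window
15 frames, edges truncated symmetrically).

**Movement state.** An interval is stationary below `min_speed_moving`
(1 px/s); otherwise forward or backward by the sign of displacement · body
axis. An axis-aligned box contains no head/tail information, so when the
caller has no head detector the body axis is approximated by the heading of
the displacement smoothed over 2 s: a reversal then appears as motion
anti-parallel to the recent dominant heading. The interface accepts
externally supplied per-frame orientation vectors, which take precedence.

**Bending angle.** Tall-or-square boxes (h ≥ w) use θ = 2·arctan(w/h); wide
boxes use θ = 2·arctan(2h/w); boxes elongated beyond
`straightness_ratio` = 4 (either orientation) are classified straight and
get no angle. Each formula yields 90° at its own symmetric case (w = h and
w = 2h respectively); the square box falls in the tall branch and reports
exactly 90°. The two formulas do *not* agree at the w = h branch boundary
(the wide form tends to 2·arctan 2 ≈ 126.9° there), so mean bending angle
should be compared only within a fixed morphology regime. The three-way rule
does not cover exotic postures (coiled-on-top, self-intersecting), for which
box geometry is genuinely ambiguous.

**Rolls.** A roll is an abrupt jump of the aspect ratio r = w/h:
|r_t − r_{t−1}| > `theta_roll` (default 0.3). A physical roll spans several
frames, so super-threshold jumps within a 0.25 s refractory window collapse
into one event. Roll frequency is the event count over total trajectory
duration.

**Curvature and omega turns.** Signed curvature uses central differences
(one-sided at the ends); positive curvature is leftward bending in the
image frame and flips sign under reflection. Samples whose
central-difference speed is below a floor get NaN — curvature is undefined
at a standstill, and the apex of a reversal is exactly such a point (the
path is not locally smooth there). The omega detector uses
`min_speed_moving` as that floor. A turn event is a local maximum of |k|
above `theta_curve` (default 0.05 px⁻¹, i.e. a turning radius under 20 px)
whose trailing-window trapezoidal integral of |k| over `curvature_window`
(default 1 s) exceeds `theta_curve · curvature_window` — the integral
condition rejects single-sample noise spikes that the peak test alone would
admit. The absolute value in the integral makes turn sharpness
sign-independent. Peaks closer than one window apart, or with prominence
below `theta_curve`/2, are merged into the higher peak: a sustained
constant-curvature excursion is one physical maneuver even though sampling
jitter gives it many numerical local maxima, while genuinely sequential
turns separated by straighter path remain distinct events.

`theta_roll`, `theta_curve`, and `curvature_window` have no canonical
published values for this box-based approach; the defaults were chosen once
on geometric grounds (a roll flips a ~2:1 silhouette, so Δr well above
frame-to-frame bending noise; an omega loop has a turning radius comparable
to a fraction of body length) and are recorded in every output's metadata.

## Detection and continuity metrics

Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean.
Evaluation matching is greedy in descending score with best-IoU tie-break at
a fixed IoU threshold (0.5 for mAP50), per frame — deliberately independent
of the tracker's Hungarian machinery so the evaluation cannot inherit a
tracker bug. AP integrates the all-point-interpolated precision envelope
over recall; with a single object class, mAP equals AP. Throughput (frames/s)
is reported in logs only and never asserted: it measures hardware, not the
algorithm.

Continuity bookkeeping associates each ground-truth identity to tracker
output per frame by best IoU (threshold 0.3): an identity switch is a frame
where a truth identity's matched track id changes; a fragmentation is a
resumption of coverage after a gap inside the identity's lifespan.

## Simulator

The simulator emulates a plate-level recording of several worms at 25
frames/s in a 1024 px arena: per-worm speeds drawn near 50 ± 10 px/s,
small wrapped-normal heading diffusion (σ = 0.01 rad/frame), and
Poisson-timed behavioral events (defaults: reversals 0.05 /s, omega turns
0.1 /s, rolls 0.1 /s per worm) thinned to at least 2.5 s separation so that
every labeled event is individually recoverable. Reversals flip the motion
direction while head orientation is kept, with a 0.1 s standstill at entry
and exit — the hesitation real worms show, which also keeps the sampled path
piecewise smooth. An omega turn drives the centroid along a deterministic
arc of radius `omega_radius` (12 px) sweeping 300°, at half the run speed,
so path curvature during the event is exactly 1/12 px⁻¹ — comfortably above
the 0.05 px⁻¹ detection threshold. Worms steer smoothly away from arena
walls inside a 2.5-body-length zone at a fixed 40 px turning radius
(curvature 0.025 px⁻¹, below threshold), because an instantaneous wall
reflection would forge a sharp-turn signature.

The body is a 30 px backbone carrying a one-wavelength sinusoidal heading
wave (amplitude 1.4 rad, 0.5 Hz) — the crawling S-posture — and the true box
is the backbone's axis-aligned bounds padded by half the 5 px body width.
During an omega turn the silhouette eases (smoothstep, 0.5 s) into the box
of the curled Ω posture, a near-closed loop whose bounding square is
rotation-invariant; this keeps frame-to-frame aspect-ratio changes well
below `theta_roll` outside seeded rolls. A roll adds `roll_ratio_amplitude`
(1.0) to the aspect ratio for 0.16 s — under the roll refractory window, so
onset and offset register as one event.

Detection rendering jitters box centers by `detection_noise_sd` (1 px) and
dimensions by half that, draws scores near 0.85 (σ = 0.05), or near 0.3
during configured occlusion episodes, optionally merges an occluded pair
into one enclosing low-score box, and drops detections at `dropout_prob`.
One master seed feeds independent substreams for motion, event times,
rendering noise, and dropout, so ablations (e.g. noise off) do not shift the
motion realization; identical seeds give bit-identical output.

The occlusion benchmark (`occlusion_scenario`) pins 5 worms on a wide grid
at 18 px/s for 200 frames with one 10-frame low-confidence episode;
placement and speed guarantee distinct worms never overlap, so any identity
error indicts the association logic rather than genuine ambiguity.

**What the simulator does not emulate:** real body deformation (the box
series comes from an idealized backbone, not pixels), detector failure modes
other than confidence dips / merges / dropped frames (no localization bias,
no double detections), larval size diversity, and contact interactions
between worms. Passing recovery tests therefore demonstrates the estimators
and tracker are correct on clean signal with calibrated noise — not that any
fixed threshold is optimal for a particular microscope.

## Numerical choices and degenerate inputs

- Empty frames, empty detection sets and empty track sets flow through every
  operation without error; readers reject malformed lines with file/line
  context rather than coercing.
- Undefined ratios (precision with no detections, curvature at standstill,
  bending angle of a straight body) are explicit markers (None/NaN), never
  silently 0.
- The Kalman update symmetrizes the posterior covariance against round-off
  and rejects non-finite states and non-positive observed heights.
- Assignment requires finite costs; gating rejects matched pairs above the
  cost gate after the global optimum is found (the standard practice, which
  can differ from re-solving with forbidden pairs — at IoU-style gates the
  difference is immaterial and the behavior is pinned by test).
- The per-second speed bins include both boundary samples so no path segment
  is lost between bins; a final bin shorter than 0.5 s is dropped.

## Known limitations

- Curvature from central differences amplifies coordinate noise as 1/Δt²;
  on raw detector output at 25 fps with ~1 px jitter, omega-turn counts are
  unreliable, and a reversal apex in a noisy path is geometrically
  indistinguishable from a sharp turn. The recovery guarantees in the test
  suite are established on ground-truth trajectories; users applying the
  curvature estimators to tracked output should smooth positions and treat
  counts as upper bounds.
- Box aspect ratio conflates rolling with fast reorientation of an
  elongated body; the roll detector is only as good as the detector's box
  tightness.
- The two-stage tracker carries no appearance features by design; worms that
  genuinely swap positions while fused into one detection cannot be
  disambiguated.
- Average-speed estimates on noisy detections inflate with the noise level
  (path length accumulates jitter); the per-second binning dampens but does
  not remove this bias.
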