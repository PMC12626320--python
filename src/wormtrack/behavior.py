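"""Locomotion parameters from per-worm trajectories.

Every estimator consumes a :class:`Trajectory` — the per-frame time series of
centroid position and bounding-box dimensions of one worm — and works in
pixels and seconds. The extracted repertoire:

- instantaneous / average / per-second-mean speed (path length over time);
- movement state (forward / backward / stationary) from the displacement's
  alignment with the body axis;
- bending angle from bounding-box diagonal geometry, with a morphology rule
  that skips essentially straight (strongly elongated) bodies;
- roll events as abrupt jumps of the box aspect ratio r = w/h between
  consecutive frames, and their frequency per second;
- signed trajectory curvature by central differences, and omega turns as
  high-curvature excursions whose windowed |curvature| integral is large.

When a physical calibration (micrometers per pixel) is supplied, summary
speeds are additionally reported on the physical scale; all internal
computation stays in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigError,
    InconsistentInputError,
    InsufficientDataError,
    InvalidBoxError,
    ZeroIntervalError,
)
from .geometry import BoundingBox

__all__ = [
    "Trajectory",
    "BehaviorConfig",
    "BehaviorEvent",
    "BehaviorSummary",
    "instantaneous_speed",
    "average_speed",
    "per_second_mean_speed",
    "smooth_speed",
    "classify_direction",
    "bending_angle",
    "detect_rolls",
    "roll_frequency",
    "curvature_profile",
    "detect_omega_turns",
    "summarize_behavior",
]


@dataclass
class Trajectory:
    """Time series of one worm: timestamps, centroids, and box dimensions."""

    track_id: int
    t: np.ndarray   # seconds, strictly increasing
    x: np.ndarray   # pixels
    y: np.ndarray   # pixels
    w: np.ndarray   # box widths, pixels
    h: np.ndarray   # box heights, pixels
    fps: float

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "w", "h"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if any(len(getattr(self, name)) != n for name in ("x", "y", "w", "h")):
            raise InconsistentInputError("trajectory series must all have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise InconsistentInputError("timestamps must be strictly increasing")
        if self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Total elapsed time in seconds."""
        return float(self.t[-1] - self.t[0])

    @classmethod
    def from_track(cls, track, fps: float) -> "Trajectory":
        """Build a trajectory from a tracker :class:`~wormtrack.tracker.Track`."""
        frames = np.array([f for f, _, _ in track.history], dtype=float)
        boxes = [b for _, b, _ in track.history]
        return cls(
            track_id=track.track_id,
            t=frames / fps,
            x=np.array([b.cx for b in boxes]),
            y=np.array([b.cy for b in boxes]),
            w=np.array([b.w for b in boxes]),
            h=np.array([b.h for b in boxes]),
            fps=fps,
        )


@dataclass(frozen=True)
class BehaviorConfig:
    """Thresholds and windows of the behavior estimators.

    theta_roll
        Minimum absolute one-frame jump of the aspect ratio w/h that counts
        as a roll (dimensionless).
    theta_curve
        Curvature threshold for omega-turn peaks (1/pixels).
    curvature_window
        Length of the sliding |curvature| integration window (seconds).
    roll_refractory
        Consecutive super-threshold aspect-ratio jumps closer than this are
        one physical roll (seconds).
    smooth_window
        Centered moving-average window for speed smoothing (frames, odd).
    straightness_ratio
        Elongation max(w/h, h/w) above which the worm is treated as straight
        and no bending angle is computed.
    min_speed_moving
        Speed below which an interval is classified stationary (pixels/s).
    heading_smooth_seconds
        Window for the slow-heading body-axis estimate used when no
        orientation series is supplied (seconds).
    pixel_scale
        Physical length of one pixel (micrometers/pixel), optional; converts
        reported summary speeds to micrometers/s.
    """

    theta_roll: float = 0.3
    theta_curve: float = 0.05
    curvature_window: float = 1.0
    roll_refractory: float = 0.25
    smooth_window: int = 15
    straightness_ratio: float = 4.0
    min_speed_moving: float = 1.0
    heading_smooth_seconds: float = 2.0
    pixel_scale: float | None = None

    def __post_init__(self) -> None:
        for name in ("theta_roll", "theta_curve", "curvature_window", "roll_refractory",
                     "straightness_ratio", "min_speed_moving", "heading_smooth_seconds"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError(f"smooth_window must be odd and >= 1, got {self.smooth_window}")
        if self.pixel_scale is not None and self.pixel_scale <= 0:
            raise ConfigError("pixel_scale must be positive when given")


@dataclass(frozen=True)
class BehaviorEvent:
    """A timestamped behavioral event with its triggering statistic."""

    kind: str  # "roll" | "omega_turn" | "reversal_onset"
    t: float
    statistic: float


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-worm aggregate of the locomotion estimators."""

    track_id: int
    mean_speed: float            # pixels/s
    roll_frequency: float        # events/s
    omega_turn_count: int
    fraction_forward: float
    fraction_backward: float
    fraction_stationary: float
    mean_bending_angle: float    # degrees; NaN when always straight
    mean_speed_physical: float | None = None  # micrometers/s when calibrated


# ------------------------------------------------------------------ speed


def instantaneous_speed(traj: Trajectory) -> np.ndarray:
    """Per-interval speed: displacement over time between consecutive samples.

    Direction is ignored; only the magnitude is reported. Returns ``n - 1``
    values for ``n`` samples.
    """
    if len(traj) < 2:
        raise InsufficientDataError("need at least 2 samples for speed")
    dt = np.diff(traj.t)
    if np.any(dt <= 0):
        raise ZeroIntervalError("duplicate or non-increasing timestamps")
    ds = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return ds / dt


def average_speed(traj: Trajectory) -> float:
    """Total path length divided by total elapsed time (pixels/s)."""
    if len(traj) < 2:
        raise InsufficientDataError("need at least 2 samples for speed")
    total_time = traj.t[-1] - traj.t[0]
    if total_time <= 0:
        raise ZeroIntervalError("trajectory spans zero time")
    ds = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return float(ds.sum() / total_time)


def per_second_mean_speed(traj: Trajectory, min_partial_bin: float = 0.5) -> float:
    """Arithmetic mean of per-1-second-bin average speeds.

    Samples are binned into consecutive 1 s windows aligned to the first
    timestamp; the path-length-over-time average speed is computed within
    each bin (bins include their boundary sample on both sides so no path
    segment is lost); a trailing partial bin shorter than ``min_partial_bin``
    seconds is dropped.
    """
    if len(traj) < 2 or traj.duration < 1.0:
        raise InsufficientDataError("trajectory must span at least 1 second")
    rel = traj.t - traj.t[0]
    bin_speeds = []
    start = 0.0
    while start < rel[-1]:
        end = start + 1.0
        mask = (rel >= start) & (rel <= end)
        idx = np.flatnonzero(mask)
        if len(idx) >= 2:
            span = rel[idx[-1]] - rel[idx[0]]
            is_trailing_partial = end > rel[-1] and (rel[-1] - start) < min_partial_bin
            if span > 0 and not is_trailing_partial:
                ds = np.hypot(np.diff(traj.x[idx]), np.diff(traj.y[idx]))
                bin_speeds.append(ds.sum() / span)
        start = end
    if not bin_speeds:
        raise InsufficientDataError("no complete 1-second bins in trajectory")
    return float(np.mean(bin_speeds))


def smooth_speed(speeds: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge windows truncate symmetrically.

    Length-preserving; a constant series is a fixed point; ``window=1`` is
    the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"smoothing window must be odd and >= 1, got {window}")
    speeds = np.asarray(speeds, dtype=float)
    if window > len(speeds):
        raise ConfigError("smoothing window longer than the series")
    half = window // 2
    out = np.empty_like(speeds)
    for i in range(len(speeds)):
        k = min(half, i, len(speeds) - 1 - i)  # symmetric truncation at edges
        out[i] = speeds[i - k : i + k + 1].mean()
    return out


# -------------------------------------------------------------- direction


def _slow_heading(traj: Trajectory, window_seconds: float) -> np.ndarray:
    """Unit body-axis proxy: displacement smoothed over a centered window.

    An axis-aligned box carries no head/tail information, so when the caller
    supplies no orientation the dominant recent heading stands in for the
    head-to-tail axis: a reversal then shows up as displacement anti-parallel
    to this slow heading.
    """
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    dt = np.diff(traj.t)
    n_frames = max(1, int(round(window_seconds * traj.fps)))
    if n_frames % 2 == 0:
        n_frames += 1
    n_frames = min(n_frames, len(dx) if len(dx) % 2 == 1 else len(dx) - 1)
    n_frames = max(n_frames, 1)
    sx = smooth_speed(dx / dt, n_frames)
    sy = smooth_speed(dy / dt, n_frames)
    norm = np.hypot(sx, sy)
    norm[norm == 0] = 1.0
    return np.stack([sx / norm, sy / norm], axis=1)


def classify_direction(
    traj: Trajectory,
    cfg: BehaviorConfig,
    orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Per-interval movement state: ``forward``, ``backward`` or ``stationary``.

    An interval is stationary when its speed is below ``min_speed_moving``;
    otherwise forward when the displacement has positive dot product with the
    body axis at the interval start, backward when negative. ``orientation``,
    when given, is an (n, 2) array of per-sample unit head-direction vectors;
    otherwise the slow-heading proxy is used (see :func:`_slow_heading`).
    """
    if len(traj) < 2:
        raise InsufficientDataError("need at least 2 samples to classify direction")
    speeds = instantaneous_speed(traj)
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    if orientation is not None:
        orientation = np.asarray(orientation, dtype=float)
        if orientation.shape != (len(traj), 2):
            raise InconsistentInputError(
                f"orientation must have shape ({len(traj)}, 2), got {orientation.shape}"
            )
        axis = orientation[:-1]
    else:
        axis = _slow_heading(traj, cfg.heading_smooth_seconds)
    dot = dx * axis[:, 0] + dy * axis[:, 1]
    out = np.where(dot > 0, "forward", "backward").astype("<U10")
    out[speeds < cfg.min_speed_moving] = "stationary"
    return out


# ---------------------------------------------------------- bending angle


def bending_angle(box: BoundingBox, cfg: BehaviorConfig) -> float | None:
    """Bending angle in degrees from box diagonal geometry, or None if straight.

    Morphology rule: strongly elongated boxes (max(w/h, h/w) above the
    straightness ratio) are treated as straight bodies and get no angle;
    tall-or-square boxes (h >= w) use theta = 2*arctan(w/h); wide boxes use
    theta = 2*arctan(2h/w). Each form yields 90 degrees at its own symmetric
    case (w = h for the tall form, w = 2h for the wide form); a square box
    falls in the tall branch and reports exactly 90 degrees.
    """
    r = box.w / box.h
    if max(r, 1.0 / r) > cfg.straightness_ratio:
        return None
    if box.h >= box.w:
        theta = 2.0 * np.arctan(box.w / box.h)
    else:
        theta = 2.0 * np.arctan(2.0 * box.h / box.w)
    return float(np.degrees(theta))


# ------------------------------------------------------------------ rolls


def detect_rolls(traj: Trajectory, cfg: BehaviorConfig) -> list[BehaviorEvent]:
    """Roll events: abrupt one-frame jumps of the box aspect ratio.

    A sample where ``|r_t - r_{t-1}| > theta_roll`` triggers an event;
    consecutive super-threshold samples within ``roll_refractory`` seconds of
    the previous event collapse into that event (a physical roll spanning
    several frames is one roll).
    """
    if len(traj) < 2:
        raise InsufficientDataError("need at least 2 samples for roll detection")
    if np.any(traj.h <= 0) or np.any(traj.w <= 0):
        raise InvalidBoxError("box dimensions must be positive")
    r = traj.w / traj.h
    jumps = np.abs(np.diff(r))
    events: list[BehaviorEvent] = []
    last_t = -np.inf
    for i in np.flatnonzero(jumps > cfg.theta_roll):
        t_event = traj.t[i + 1]
        if t_event - last_t > cfg.roll_refractory:
            events.append(BehaviorEvent(kind="roll", t=float(t_event), statistic=float(jumps[i])))
        last_t = t_event
    return events


def roll_frequency(events: list[BehaviorEvent], traj: Trajectory) -> float:
    """Roll events per second over the whole trajectory duration."""
    if traj.duration <= 0:
        raise ZeroIntervalError("trajectory duration must be positive")
    return len([e for e in events if e.kind == "roll"]) / traj.duration


# -------------------------------------------------------------- curvature


def curvature_profile(traj: Trajectory, min_speed: float = 1e-6) -> np.ndarray:
    """Signed curvature k = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2) per sample.

    Derivatives use central differences (one-sided at the endpoints);
    positive curvature is leftward bending in the image frame. Samples whose
    central-difference speed falls below ``min_speed`` (pixels/s) get NaN —
    curvature is undefined at a standstill or at the apex of a perfect
    reversal, where the path is not locally smooth.
    """
    if len(traj) < 3:
        raise InsufficientDataError("need at least 3 samples for curvature")
    xd = np.gradient(traj.x, traj.t)
    yd = np.gradient(traj.y, traj.t)
    xdd = np.gradient(xd, traj.t)
    ydd = np.gradient(yd, traj.t)
    speed2 = xd**2 + yd**2
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (xd * ydd - yd * xdd) / speed2**1.5
    k[speed2 < min_speed**2] = np.nan
    return k


def detect_omega_turns(traj: Trajectory, cfg: BehaviorConfig) -> list[BehaviorEvent]:
    """Omega-turn events from high-curvature excursions of the trajectory.

    A turn is a local maximum of |k| exceeding ``theta_curve`` whose windowed
    integral S(t) = int_{t-dt}^{t} |k(tau)| d tau (trapezoidal, window
    ``curvature_window``) also exceeds ``theta_curve * curvature_window``.
    Each super-threshold peak is a distinct event: a single-peak signature is
    one rapid turn; a multi-peak pattern is a sequence of turns. Peaks closer
    than one curvature window apart, or with prominence under half the
    threshold, are one maneuver (the higher peak wins), so sampling jitter on
    a sustained curvature plateau cannot multiply a single physical turn. Undefined (NaN) curvature samples contribute zero
    to the integral and cannot be peaks.
    """
    import scipy.signal

    # below walking speed the path direction is noise-dominated (and exactly
    # at a reversal apex the path is not smooth): curvature is undefined there
    k = curvature_profile(traj, min_speed=cfg.min_speed_moving)
    n_window = int(round(cfg.curvature_window * traj.fps))
    if n_window < 1 or n_window >= len(traj):
        raise ConfigError("curvature_window must fit inside the trajectory")
    abs_k = np.abs(k)
    abs_k_filled = np.where(np.isnan(abs_k), 0.0, abs_k)

    # sliding trailing-window trapezoidal integral of |k|
    trap = np.zeros_like(abs_k_filled)
    trap[1:] = (abs_k_filled[1:] + abs_k_filled[:-1]) / 2.0 * np.diff(traj.t)
    cum = np.concatenate([[0.0], np.cumsum(trap)])
    s = np.full(len(abs_k_filled), np.nan)
    for i in range(n_window, len(abs_k_filled)):
        s[i] = cum[i + 1] - cum[i + 1 - n_window]

    peaks, props = scipy.signal.find_peaks(
        abs_k_filled,
        height=cfg.theta_curve,
        distance=n_window,
        prominence=cfg.theta_curve / 2.0,
    )
    events: list[BehaviorEvent] = []
    s_threshold = cfg.theta_curve * cfg.curvature_window
    for p, height in zip(peaks, props["peak_heights"]):
        # the windowed integral may peak after |k| does; look ahead one window
        j0, j1 = p, min(p + n_window, len(s) - 1)
        window_s = s[j0 : j1 + 1]
        window_s = window_s[~np.isnan(window_s)]
        if len(window_s) and window_s.max() >= s_threshold:
            events.append(
                BehaviorEvent(kind="omega_turn", t=float(traj.t[p]), statistic=float(height))
            )
    return events


# ---------------------------------------------------------------- summary


def summarize_behavior(
    traj: Trajectory,
    cfg: BehaviorConfig | None = None,
    orientation: np.ndarray | None = None,
) -> BehaviorSummary:
    """Aggregate every estimator into one per-worm record.

    ``mean_speed`` is the per-second arithmetic mean of 1 s-bin average
    speeds; the forward/backward/stationary fractions are duration-weighted
    over classified intervals and sum to 1.
    """
    if cfg is None:
        cfg = BehaviorConfig()
    if traj.duration < 1.0:
        raise InsufficientDataError("trajectory must span at least 1 second")

    speed = per_second_mean_speed(traj)
    rolls = detect_rolls(traj, cfg)
    omegas = detect_omega_turns(traj, cfg)
    states = classify_direction(traj, cfg, orientation)
    dt = np.diff(traj.t)
    total = dt.sum()
    frac = {
        name: float(dt[states == name].sum() / total)
        for name in ("forward", "backward", "stationary")
    }
    angles = [
        bending_angle(BoundingBox(cx=0.0, cy=0.0, w=w, h=h), cfg)
        for w, h in zip(traj.w, traj.h)
    ]
    defined = [a for a in angles if a is not None]
    mean_angle = float(np.mean(defined)) if defined else float("nan")
    return BehaviorSummary(
        track_id=traj.track_id,
        mean_speed=speed,
        roll_frequency=roll_frequency(rolls, traj),
        omega_turn_count=len(omegas),
        fraction_forward=frac["forward"],
        fraction_backward=frac["backward"],
        fraction_stationary=frac["stationary"],
        mean_bending_angle=mean_angle,
        mean_speed_physical=(speed * cfg.pixel_scale if cfg.pixel_scale else None),
    )
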