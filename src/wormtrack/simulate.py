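"""Seeded multi-worm detection-stream simulator with ground-truth labels.

The simulator stands in for a recorded video plus a trained detector: it
generates per-worm trajectories from a run-and-turn process and renders them
into noisy per-frame bounding-box detections.

Motion model (per worm, per frame):

- a persistent heading with small wrapped-normal angular diffusion (runs);
- Poisson-timed reversals: the worm pauses briefly, backs up along its body
  axis for a fixed duration while its head orientation is unchanged, pauses
  again, and resumes forward motion (the pauses reproduce the hesitation at
  direction changes and keep the path piecewise-smooth);
- Poisson-timed omega turns: the centroid follows a deterministic arc of the
  configured radius sweeping >= 270 degrees, so the path curvature during
  the event is exactly 1/omega_radius;
- Poisson-timed rolls: transient excursions of the box aspect ratio of the
  configured amplitude (a body flip changes the apparent silhouette, not the
  centroid path);
- gentle steering away from the arena walls inside a boundary zone, at a
  bounded turn rate whose path curvature stays well below the omega-turn
  threshold (an instantaneous reflection would fake a sharp-turn signature).

The body is rendered as a fixed-length backbone carrying a sinusoidal
traveling curvature wave (the crawling S-posture) that morphs into a
near-closed constant-curvature curl during an omega turn; the per-frame true
box is the axis-aligned bounds of this backbone plus half the body width.
Worms therefore always present a compact curved silhouette, and box
dimensions evolve smoothly between frames — abrupt aspect-ratio jumps occur
only at seeded roll events.

Detection rendering jitters the true boxes, draws confidence scores near a
high mean (or near a low mean during configured occlusion episodes), drops
frames at the configured rate, and can merge an occluded pair into one
enclosing low-score box.

One global seed drives independent substreams for motion, event times,
scores/noise and dropout, so switching noise off does not shift the motion
realization. Identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .behavior import Trajectory
from .errors import ConfigError
from .geometry import BoundingBox, Detection

__all__ = [
    "SimConfig",
    "OcclusionEpisode",
    "LabeledEvent",
    "GroundTruth",
    "simulate",
    "render_detections",
    "make_fixture_dataset",
    "occlusion_scenario",
]

_STREAM_MOTION = 101
_STREAM_EVENTS = 202
_STREAM_RENDER = 303
_STREAM_DROPOUT = 404


@dataclass(frozen=True)
class OcclusionEpisode:
    """A window where a worm pair's detections are occlusion-degraded."""

    worm_a: int
    worm_b: int
    start_frame: int
    n_frames: int
    merge: bool = False  # emit one enclosing low-score box for the pair


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated recording.

    Rates are per worm per second; geometry is in pixels, time in seconds.
    Defaults emulate a plate-level recording of adult worms at moderate
    magnification: a 1024 px arena, 25 frames/s, crawling speeds of tens of
    pixels per second, and a behavioral repertoire of roughly one reversal,
    two omega turns and two rolls per worm over a 20 s clip.
    """

    n_worms: int = 3
    arena: tuple[float, float] = (1024.0, 1024.0)
    fps: float = 25.0
    duration: float = 20.0
    speed_mean: float = 50.0
    speed_sd: float = 10.0
    reversal_rate: float = 0.05
    reversal_duration: float = 1.0
    reversal_pause: float = 0.1       # s standstill at reversal entry and exit
    omega_rate: float = 0.1
    omega_radius: float = 12.0
    omega_sweep_deg: float = 300.0
    omega_body_sweep: float = 5.3     # rad the body curls into during a turn (the Ω posture)
    omega_speed_factor: float = 0.5   # worms slow down while executing a turn
    roll_rate: float = 0.1
    roll_ratio_amplitude: float = 1.0
    roll_duration: float = 0.16
    body_length: float = 30.0
    body_width: float = 5.0
    heading_diffusion: float = 0.01   # rad per frame (sd)
    bend_amp: float = 1.4             # peak heading deviation along the body (rad)
    bend_freq: float = 0.5            # Hz of the undulation wave
    event_spacing: float = 2.5        # min separation between seeded events (s)
    detection_noise_sd: float = 1.0
    score_high_mean: float = 0.85
    score_occluded_mean: float = 0.3
    score_sd: float = 0.05
    dropout_prob: float = 0.0
    occlusion_episodes: tuple[OcclusionEpisode, ...] = ()
    init_positions: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_worms < 1:
            raise ConfigError("n_worms must be >= 1")
        for name in ("reversal_rate", "omega_rate", "roll_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("dropout_prob",):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if min(self.arena) <= 4 * self.body_length:
            raise ConfigError(
                f"arena {self.arena} too small for body length {self.body_length}"
            )
        if self.omega_sweep_deg < 270:
            raise ConfigError("omega_sweep_deg must be >= 270 for an omega-shaped loop")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


@dataclass(frozen=True)
class LabeledEvent:
    worm: int
    kind: str   # "reversal" | "omega_turn" | "roll"
    t: float    # onset (reversal) or apex (omega) or onset (roll), seconds
    t_end: float


@dataclass
class GroundTruth:
    """Everything the simulator knows: true motion, orientation, and labels."""

    config: SimConfig
    trajectories: dict[int, Trajectory]
    orientations: dict[int, np.ndarray]          # (n, 2) unit head-direction vectors
    events: list[LabeledEvent]
    boxes: dict[int, list[tuple[int, BoundingBox]]]  # frame -> [(worm, box)]

    def events_of(self, kind: str, worm: int | None = None) -> list[LabeledEvent]:
        return [
            e for e in self.events
            if e.kind == kind and (worm is None or e.worm == worm)
        ]

    def true_states(self, worm: int) -> np.ndarray:
        """Per-interval forward/backward/stationary labels from the schedule.

        The brief standstills buffering each reversal are labeled stationary.
        """
        traj = self.trajectories[worm]
        pause = self.config.reversal_pause
        mid = (traj.t[:-1] + traj.t[1:]) / 2.0
        out = np.full(len(mid), "forward", dtype="<U10")
        for ev in self.events_of("reversal", worm):
            out[(mid >= ev.t) & (mid < ev.t_end)] = "backward"
            out[(mid >= ev.t) & (mid < ev.t + pause)] = "stationary"
            out[(mid >= ev.t_end - pause) & (mid < ev.t_end)] = "stationary"
        return out


def _sample_event_times(
    rng: np.random.Generator, cfg: SimConfig
) -> list[tuple[str, float, float]]:
    """Poisson event times for one worm, thinned to non-overlapping windows."""
    sweep = math.radians(cfg.omega_sweep_deg)
    candidates: list[tuple[str, float, float]] = []
    specs = (
        ("reversal", cfg.reversal_rate, cfg.reversal_duration),
        ("omega_turn", cfg.omega_rate, None),  # duration depends on worm speed; bounded below
        ("roll", cfg.roll_rate, cfg.roll_duration),
    )
    margin = 1.5  # keep events clear of the clip boundaries
    for kind, rate, dur in specs:
        n = rng.poisson(rate * cfg.duration)
        times = np.sort(rng.uniform(margin, max(margin, cfg.duration - margin - 1.0), size=n))
        for t0 in times:
            d = dur if dur is not None else sweep * cfg.omega_radius / max(
                cfg.omega_speed_factor * cfg.speed_mean, 1e-9
            )
            candidates.append((kind, float(t0), float(t0 + d)))
    candidates.sort(key=lambda e: e[1])
    kept: list[tuple[str, float, float]] = []
    for ev in candidates:
        if not kept or ev[1] >= kept[-1][2] + cfg.event_spacing:
            kept.append(ev)
    return kept


def _body_box(
    pos: np.ndarray,
    phi: float,
    wave_phase: float,
    cfg: SimConfig,
    n_pts: int = 21,
) -> BoundingBox:
    """Axis-aligned box of the undulating backbone centered at ``pos``.

    The backbone of length ``body_length`` carries a one-wavelength
    sinusoidal heading wave of amplitude ``bend_amp`` at phase ``wave_phase``
    (the crawling S-posture). Mean tangent direction is ``phi``, centroid is
    ``pos``; the box pads by half the body width on every side.
    """
    length = cfg.body_length
    s = np.linspace(0.0, length, n_pts)
    theta = cfg.bend_amp * np.sin(2 * math.pi * s / length - wave_phase)
    theta = theta - theta.mean() + phi
    ds = length / (n_pts - 1)
    bx = np.concatenate([[0.0], np.cumsum(np.cos(theta[:-1]) + np.cos(theta[1:]))]) * ds / 2
    by = np.concatenate([[0.0], np.cumsum(np.sin(theta[:-1]) + np.sin(theta[1:]))]) * ds / 2
    bx, by = bx - bx.mean(), by - by.mean()
    half = cfg.body_width / 2.0
    w = bx.max() - bx.min() + 2 * half
    h = by.max() - by.min() + 2 * half
    cx = pos[0] + (bx.max() + bx.min()) / 2.0
    cy = pos[1] + (by.max() + by.min()) / 2.0
    return BoundingBox(cx=cx, cy=cy, w=w, h=h)


def _curl_box(pos: np.ndarray, cfg: SimConfig) -> BoundingBox:
    """Box of the omega posture: the body curled into a near-closed loop.

    A loop of total bend ``omega_body_sweep`` has diameter 2L/sweep; its
    bounding box is square and rotation-invariant.
    """
    d = 2.0 * cfg.body_length / cfg.omega_body_sweep + cfg.body_width
    return BoundingBox(cx=pos[0], cy=pos[1], w=d, h=d)


def simulate(cfg: SimConfig) -> GroundTruth:
    """Generate ground-truth motion, boxes and event labels for one clip."""
    rng_motion = np.random.default_rng([cfg.seed, _STREAM_MOTION])
    rng_events = np.random.default_rng([cfg.seed, _STREAM_EVENTS])
    n = cfg.n_frames
    dt = 1.0 / cfg.fps
    t = np.arange(n) * dt
    aw, ah = cfg.arena
    margin = cfg.body_length

    # initial placement: supplied, or rejection-sampled for pairwise separation
    if cfg.init_positions is not None:
        if len(cfg.init_positions) != cfg.n_worms:
            raise ConfigError("init_positions length must equal n_worms")
        starts = [np.array(p, dtype=float) for p in cfg.init_positions]
    else:
        starts = []
        min_sep = 3 * cfg.body_length
        for _ in range(cfg.n_worms):
            for _attempt in range(1000):
                p = rng_motion.uniform([margin, margin], [aw - margin, ah - margin])
                if all(np.hypot(*(p - q)) >= min_sep for q in starts):
                    starts.append(p)
                    break
            else:
                raise ConfigError("could not place worms with the required separation")

    trajectories: dict[int, Trajectory] = {}
    orientations: dict[int, np.ndarray] = {}
    all_events: list[LabeledEvent] = []
    boxes: dict[int, list[tuple[int, BoundingBox]]] = {f: [] for f in range(n)}

    omega_ramp = 0.5  # s over which the body curls into / out of the turn posture

    for worm in range(cfg.n_worms):
        speed = max(float(rng_motion.normal(cfg.speed_mean, cfg.speed_sd)), 5.0)
        phi = float(rng_motion.uniform(0, 2 * math.pi))
        bend_phase = float(rng_motion.uniform(0, 2 * math.pi))
        bend_sign = 1.0 if rng_motion.random() < 0.5 else -1.0
        steps = rng_motion.normal(0.0, cfg.heading_diffusion, size=n)

        events = _sample_event_times(rng_events, cfg)
        omega_sweep_path = math.radians(cfg.omega_sweep_deg)
        omega_dur = omega_sweep_path * cfg.omega_radius / (cfg.omega_speed_factor * speed)
        schedule = []
        for kind, t0, t1 in events:
            if kind == "omega_turn":
                t1 = t0 + omega_dur
            schedule.append((kind, t0, t1))

        pos = starts[worm].copy()
        xs = np.empty(n); ys = np.empty(n)
        ws = np.empty(n); hs = np.empty(n)
        heads = np.empty((n, 2))
        for i in range(n):
            ti = t[i]
            mode = "run"
            ev_t0 = ev_t1 = 0.0
            for kind, t0, t1 in schedule:
                if t0 <= ti < t1:
                    mode, ev_t0, ev_t1 = kind, t0, t1
                    break
            if mode == "omega_turn":
                phi += bend_sign * (cfg.omega_speed_factor * speed / cfg.omega_radius) * dt
            else:
                phi += steps[i]
                # steer smoothly away from walls inside the boundary zone;
                # turn-rate curvature steer_rate/speed stays below the
                # omega-turn detection threshold
                zone = 2.5 * cfg.body_length
                dx_in = 1.0 if pos[0] < zone else (-1.0 if pos[0] > aw - zone else 0.0)
                dy_in = 1.0 if pos[1] < zone else (-1.0 if pos[1] > ah - zone else 0.0)
                if dx_in or dy_in:
                    # fixed turning radius: path curvature 1/steer_radius is
                    # speed-independent and below the turn-detection threshold
                    steer_radius = 40.0
                    steer_rate = speed / steer_radius  # rad/s
                    motion_ang = phi + (math.pi if mode == "reversal" else 0.0)
                    diff = math.atan2(dy_in, dx_in) - motion_ang
                    diff = (diff + math.pi) % (2 * math.pi) - math.pi
                    phi += float(np.clip(diff, -steer_rate * dt, steer_rate * dt))
            head = np.array([math.cos(phi), math.sin(phi)])
            direction = -head if mode == "reversal" else head
            step_speed = speed
            if mode == "omega_turn":
                step_speed = cfg.omega_speed_factor * speed
            if mode == "reversal" and (
                ti - ev_t0 < cfg.reversal_pause or ev_t1 - ti < cfg.reversal_pause
            ):
                step_speed = 0.0  # standstill buffers the direction flip
            pos = pos + step_speed * dt * direction
            # last-resort clamp well inside the steering zone, loose enough
            # that an omega loop at the zone edge is never clipped
            clamp = 1.5 * cfg.body_width
            pos = np.clip(pos, [clamp, clamp], [aw - clamp, ah - clamp])

            wave_phase = 2 * math.pi * cfg.bend_freq * ti + bend_phase
            box = _body_box(pos, phi, wave_phase, cfg)
            if mode == "omega_turn":
                # the body curls into the nearly closed Ω loop, whose box is
                # rotation-invariant; ease the silhouette in and out smoothly
                lam = min(1.0, (ti - ev_t0) / omega_ramp, (ev_t1 - ti) / omega_ramp)
                lam = max(lam, 0.0)
                lam = lam * lam * (3.0 - 2.0 * lam)  # smoothstep easing
                curl = _curl_box(pos, cfg)
                box = BoundingBox(
                    cx=(1 - lam) * box.cx + lam * curl.cx,
                    cy=(1 - lam) * box.cy + lam * curl.cy,
                    w=(1 - lam) * box.w + lam * curl.w,
                    h=(1 - lam) * box.h + lam * curl.h,
                )
            if mode == "roll":
                # body flip: transient aspect-ratio excursion, centroid unchanged
                box = BoundingBox(
                    cx=box.cx, cy=box.cy,
                    w=box.w + cfg.roll_ratio_amplitude * box.h, h=box.h,
                )
            # the true centroid is the kinematic body midpoint; the box (for
            # detection rendering and w/h series) is fitted around the bent body
            xs[i], ys[i] = pos[0], pos[1]
            ws[i], hs[i] = box.w, box.h
            heads[i] = head
            boxes[i].append((worm, box))

        trajectories[worm] = Trajectory(
            track_id=worm, t=t.copy(), x=xs, y=ys, w=ws, h=hs, fps=cfg.fps
        )
        orientations[worm] = heads
        for kind, t0, t1 in schedule:
            label_t = (t0 + t1) / 2.0 if kind == "omega_turn" else t0
            all_events.append(LabeledEvent(worm=worm, kind=kind, t=label_t, t_end=t1))

    return GroundTruth(
        config=cfg,
        trajectories=trajectories,
        orientations=orientations,
        events=sorted(all_events, key=lambda e: (e.t, e.worm)),
        boxes=boxes,
    )


def render_detections(truth: GroundTruth, cfg: SimConfig | None = None) -> dict[int, list[Detection]]:
    """Render ground-truth boxes into a noisy per-frame detection stream."""
    if cfg is None:
        cfg = truth.config
    rng = np.random.default_rng([cfg.seed, _STREAM_RENDER])
    rng_drop = np.random.default_rng([cfg.seed, _STREAM_DROPOUT])

    episodes_by_frame: dict[int, list[OcclusionEpisode]] = {}
    for ep in cfg.occlusion_episodes:
        for f in range(ep.start_frame, ep.start_frame + ep.n_frames):
            episodes_by_frame.setdefault(f, []).append(ep)

    stream: dict[int, list[Detection]] = {}
    for frame in sorted(truth.boxes):
        dets: list[Detection] = []
        eps = episodes_by_frame.get(frame, [])
        merged_pairs = [ep for ep in eps if ep.merge]
        merged_worms = {w for ep in merged_pairs for w in (ep.worm_a, ep.worm_b)}
        occluded_worms = {w for ep in eps for w in (ep.worm_a, ep.worm_b)}

        for ep in merged_pairs:
            pair_boxes = [b for w, b in truth.boxes[frame] if w in (ep.worm_a, ep.worm_b)]
            if len(pair_boxes) == 2:
                x1 = min(b.x1 for b in pair_boxes); y1 = min(b.y1 for b in pair_boxes)
                x2 = max(b.x2 for b in pair_boxes); y2 = max(b.y2 for b in pair_boxes)
                score = float(np.clip(rng.normal(cfg.score_occluded_mean, cfg.score_sd), 0.02, 1.0))
                if rng_drop.random() >= cfg.dropout_prob:
                    dets.append(Detection(
                        box=BoundingBox.from_xyxy(x1, y1, x2, y2), score=score, frame=frame
                    ))

        for worm, box in truth.boxes[frame]:
            if worm in merged_worms:
                continue
            jitter = rng.normal(0.0, cfg.detection_noise_sd, size=2)
            dim_jitter = rng.normal(0.0, cfg.detection_noise_sd / 2.0, size=2)
            mean = cfg.score_occluded_mean if worm in occluded_worms else cfg.score_high_mean
            score = float(np.clip(rng.normal(mean, cfg.score_sd), 0.02, 1.0))
            dropped = rng_drop.random() < cfg.dropout_prob
            if dropped:
                continue
            dets.append(Detection(
                box=BoundingBox(
                    cx=box.cx + jitter[0],
                    cy=box.cy + jitter[1],
                    w=max(box.w + dim_jitter[0], 2.0),
                    h=max(box.h + dim_jitter[1], 2.0),
                ),
                score=score,
                frame=frame,
            ))
        stream[frame] = dets
    return stream


def make_fixture_dataset(
    total: int | SimConfig,
    split_fractions: tuple[float, ...] = (0.8, 0.1, 0.1),
    seed: int = 0,
    names: tuple[str, ...] | None = None,
) -> dict[str, list[int]]:
    """Deterministically partition frame indices into dataset-split manifests.

    Split sizes are the rounded fractions of the total, with any rounding
    remainder assigned to the largest split, so sizes always sum exactly to
    the total. Fractions must be positive and sum to 1.
    """
    n = total.n_frames if isinstance(total, SimConfig) else int(total)
    fracs = [float(f) for f in split_fractions]
    if any(f <= 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
        raise ConfigError(f"split fractions must be positive and sum to 1, got {fracs}")
    if names is None:
        names = ("train", "val", "test") if len(fracs) == 3 else tuple(
            f"split_{i}" for i in range(len(fracs))
        )
    if len(names) != len(fracs):
        raise ConfigError("names and split_fractions must have equal length")
    sizes = [int(round(f * n)) for f in fracs]
    sizes[int(np.argmax(sizes))] += n - sum(sizes)
    if min(sizes) < 0:
        raise ConfigError("rounded split sizes became negative")
    order = np.random.default_rng(seed).permutation(n)
    out: dict[str, list[int]] = {}
    pos = 0
    for name, size in zip(names, sizes):
        out[name] = [int(i) for i in order[pos : pos + size]]
        pos += size
    return out


def occlusion_scenario(seed: int = 0, merge: bool = False) -> SimConfig:
    """The 5-worm, 200-frame occlusion benchmark configuration.

    Five well-separated worms crawl for 8 s at 25 frames/s; one pair's
    detections drop to low confidence (below the default tau_high, above
    tau_low) for a 10-frame occlusion episode mid-clip. Placement and speed
    keep distinct worms from ever overlapping, so identity errors can only
    come from the association logic, not from genuine ambiguity.
    """
    return SimConfig(
        n_worms=5,
        arena=(1200.0, 800.0),
        fps=25.0,
        duration=8.0,
        speed_mean=18.0,
        speed_sd=0.0,
        reversal_rate=0.0,
        omega_rate=0.0,
        roll_rate=0.0,
        dropout_prob=0.0,
        init_positions=((200.0, 200.0), (600.0, 200.0), (1000.0, 200.0),
                        (400.0, 600.0), (800.0, 600.0)),
        occlusion_episodes=(OcclusionEpisode(worm_a=0, worm_b=1, start_frame=95,
                                             n_frames=10, merge=merge),),
        seed=seed,
    )
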