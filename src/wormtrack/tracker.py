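"""Two-stage confidence-aware association of detections into track identities.

Each identity is maintained by a constant-velocity Kalman filter over the
state (cx, cy, r, h) plus per-frame velocities, where r = w/h is the box
aspect ratio. Per frame, detections are split by confidence: high-score
boxes are matched to active tracks first (IoU cost, Hungarian assignment);
surviving active tracks are then matched against the low-score boxes rather
than discarding them, which preserves identities through occlusion-induced
confidence dips. Unmatched high-score boxes are tried against lost tracks
(reactivation) before founding new identities.

Process/measurement noise follows the standard height-scaled parametrization
of tracking-by-detection practice: position noise ~ h/20, velocity noise
~ h/160 per frame.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .errors import (
    ConfigError,
    InconsistentInputError,
    InvalidBoxError,
    InvalidCostError,
    NumericalStateError,
    OrderingError,
)
from .geometry import BoundingBox, Detection, iou

__all__ = [
    "KalmanState",
    "TrackStatus",
    "Track",
    "TrackerConfig",
    "kalman_predict",
    "kalman_update",
    "initiate_state",
    "state_to_box",
    "cost_matrix",
    "solve_assignment",
    "associate_frame",
    "run_tracker",
]

_STD_POS = 1.0 / 20.0   # position noise scale, in units of box height
_STD_VEL = 1.0 / 160.0  # velocity noise scale, in units of box height

_NDIM = 4
_F = np.eye(2 * _NDIM)
_F[:_NDIM, _NDIM:] = np.eye(_NDIM)  # constant-velocity transition, dt = 1 frame
_H = np.eye(_NDIM, 2 * _NDIM)


@dataclass(frozen=True)
class KalmanState:
    """Gaussian filter state: 8-vector mean and 8x8 covariance.

    Mean layout: (cx, cy, r, h, vcx, vcy, vr, vh) with velocities per frame.
    """

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))
        if self.mean.shape != (8,) or self.covariance.shape != (8, 8):
            raise ValueError("KalmanState requires an 8-vector mean and 8x8 covariance")


class TrackStatus(enum.Enum):
    ACTIVE = "active"
    LOST = "lost"
    REMOVED = "removed"


@dataclass
class Track:
    """A persistent worm identity with its filter state and box history."""

    track_id: int
    state: KalmanState
    status: TrackStatus = TrackStatus.ACTIVE
    frames_since_update: int = 0
    score: float = 1.0
    history: list[tuple[int, BoundingBox, float]] = field(default_factory=list)

    @property
    def box(self) -> BoundingBox:
        """Box implied by the current filter mean."""
        return state_to_box(self.state)

    @property
    def first_frame(self) -> int:
        return self.history[0][0]

    @property
    def last_frame(self) -> int:
        return self.history[-1][0]


@dataclass(frozen=True)
class TrackerConfig:
    """Thresholds of the two-stage association.

    tau_high/tau_low split detections into high- and low-confidence groups;
    tau_init is the minimum score for founding a new identity. IoU gates are
    minimum overlaps for accepting a match (stage 1: high boxes vs active
    tracks and lost-track reactivation; stage 2: low boxes vs remaining
    active tracks). A lost track is dropped after max_lost_frames without a
    match.
    """

    tau_high: float = 0.6
    tau_low: float = 0.1
    tau_init: float = 0.7
    iou_gate_stage1: float = 0.2
    iou_gate_stage2: float = 0.5
    max_lost_frames: int = 30
    process_noise_scale: float = 1.0
    measurement_noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau_low < self.tau_high <= 1.0):
            raise ConfigError(f"need 0 <= tau_low < tau_high <= 1, got {self.tau_low}, {self.tau_high}")
        for name in ("tau_init", "iou_gate_stage1", "iou_gate_stage2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.max_lost_frames < 0:
            raise ConfigError(f"max_lost_frames must be >= 0, got {self.max_lost_frames}")
        if self.process_noise_scale <= 0 or self.measurement_noise_scale <= 0:
            raise ConfigError("noise scales must be positive")


# ---------------------------------------------------------------- Kalman


def _measurement(box: BoundingBox) -> np.ndarray:
    return np.array([box.cx, box.cy, box.w / box.h, box.h], dtype=float)


def state_to_box(state: KalmanState) -> BoundingBox:
    """Box implied by a filter mean (cx, cy, r, h)."""
    cx, cy, r, h = state.mean[:4]
    return BoundingBox(cx=cx, cy=cy, w=max(r * h, 1e-9), h=max(h, 1e-9))


def initiate_state(box: BoundingBox) -> KalmanState:
    """Start a filter at an observed box with zero velocity and wide covariance."""
    mean = np.zeros(8)
    mean[:4] = _measurement(box)
    h = box.h
    std = np.array(
        [2 * _STD_POS * h, 2 * _STD_POS * h, 1e-2, 2 * _STD_POS * h,
         10 * _STD_VEL * h, 10 * _STD_VEL * h, 1e-5, 10 * _STD_VEL * h]
    )
    return KalmanState(mean=mean, covariance=np.diag(std**2))


def kalman_predict(state: KalmanState, process_noise_scale: float = 1.0) -> KalmanState:
    """Project the state one frame ahead under constant velocity."""
    if not (np.all(np.isfinite(state.mean)) and np.all(np.isfinite(state.covariance))):
        raise NumericalStateError("non-finite Kalman state")
    h = max(state.mean[3], 1e-9)
    std = np.array(
        [_STD_POS * h, _STD_POS * h, 1e-2, _STD_POS * h,
         _STD_VEL * h, _STD_VEL * h, 1e-5, _STD_VEL * h]
    )
    q = np.diag(std**2) * process_noise_scale
    mean = _F @ state.mean
    cov = _F @ state.covariance @ _F.T + q
    return KalmanState(mean=mean, covariance=cov)


def kalman_update(
    state: KalmanState, obs: BoundingBox, measurement_noise_scale: float = 1.0
) -> KalmanState:
    """Correct a predicted state with an observed box."""
    if obs.h <= 0 or obs.w <= 0:
        raise InvalidBoxError("observation box must have positive dimensions")
    h = max(state.mean[3], 1e-9)
    std = np.array([_STD_POS * h, _STD_POS * h, 1e-1, _STD_POS * h])
    r = np.diag(std**2) * measurement_noise_scale
    z = _measurement(obs)

    s = _H @ state.covariance @ _H.T + r
    k = np.linalg.solve(s.T, (_H @ state.covariance.T)).T  # Kalman gain
    innovation = z - _H @ state.mean
    mean = state.mean + k @ innovation
    cov = (np.eye(8) - k @ _H) @ state.covariance
    cov = (cov + cov.T) / 2.0  # enforce symmetry against round-off
    if mean[3] <= 0:
        raise NumericalStateError("height component became non-positive after update")
    return KalmanState(mean=mean, covariance=cov)


# ------------------------------------------------------------ association


def cost_matrix(tracks: list[Track], detections: list[Detection]) -> np.ndarray:
    """(1 - IoU) cost between each track's predicted box and each detection."""
    costs = np.ones((len(tracks), len(detections)))
    for i, trk in enumerate(tracks):
        pbox = trk.box
        for j, det in enumerate(detections):
            costs[i, j] = 1.0 - iou(pbox, det.box)
    return costs


def solve_assignment(
    costs: np.ndarray, gate: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost bipartite matching with a cost gate.

    Returns ``(matches, unmatched_rows, unmatched_cols)``. Pairs whose cost
    exceeds ``gate`` are rejected and both members reported unmatched. Ties
    between equal-cost optimal matchings resolve to the solver's
    deterministic lowest-index preference.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.size == 0:
        return [], list(range(costs.shape[0])), list(range(costs.shape[1]))
    if not np.all(np.isfinite(costs)):
        raise InvalidCostError("cost matrix contains non-finite entries")
    rows, cols = scipy.optimize.linear_sum_assignment(costs)
    matches = []
    matched_rows: set[int] = set()
    matched_cols: set[int] = set()
    for i, j in zip(rows, cols):
        if costs[i, j] <= gate:
            matches.append((int(i), int(j)))
            matched_rows.add(int(i))
            matched_cols.add(int(j))
    unmatched_rows = [i for i in range(costs.shape[0]) if i not in matched_rows]
    unmatched_cols = [j for j in range(costs.shape[1]) if j not in matched_cols]
    return matches, unmatched_rows, unmatched_cols


def _apply_match(track: Track, det: Detection, cfg: TrackerConfig) -> None:
    track.state = kalman_update(track.state, det.box, cfg.measurement_noise_scale)
    track.status = TrackStatus.ACTIVE
    track.frames_since_update = 0
    track.score = det.score
    track.history.append((det.frame, det.box, det.score))


def associate_frame(
    tracks: list[Track],
    detections: list[Detection],
    cfg: TrackerConfig,
    next_id: int | None = None,
) -> tuple[list[Track], int]:
    """Run the two-stage association for one frame, in place on ``tracks``.

    Tracks must already be predicted to the detections' frame. Returns the
    updated track list (removed tracks retained, flagged REMOVED) and the
    next unused track id.

    Per-frame procedure:

    1. split detections at tau_high / tau_low into high and low groups
       (scores below tau_low are dropped outright);
    2. Hungarian-match high detections to active tracks (stage-1 IoU gate);
    3. Hungarian-match surviving active tracks to low detections (stage-2
       gate) — the low-confidence retention step;
    4. match remaining high detections against lost tracks, reactivating on
       success;
    5. unmatched high detections with score >= tau_init found new tracks;
       unmatched low detections are discarded;
    6. unmatched active tracks become lost; lost tracks beyond
       max_lost_frames become removed.
    """
    frames = {d.frame for d in detections}
    if len(frames) > 1:
        raise InconsistentInputError(f"detections span multiple frames: {sorted(frames)}")
    if next_id is None:
        next_id = 1 + max((t.track_id for t in tracks), default=0)

    high = [d for d in detections if d.score >= cfg.tau_high]
    low = [d for d in detections if cfg.tau_low <= d.score < cfg.tau_high]

    active = [t for t in tracks if t.status is TrackStatus.ACTIVE]
    lost = [t for t in tracks if t.status is TrackStatus.LOST]

    # stage 1: high-score detections vs active tracks
    m1, u_trk1, u_det1 = solve_assignment(cost_matrix(active, high), 1.0 - cfg.iou_gate_stage1)
    for ti, dj in m1:
        _apply_match(active[ti], high[dj], cfg)

    # stage 2: surviving active tracks vs low-score detections
    remaining_active = [active[i] for i in u_trk1]
    m2, u_trk2, _ = solve_assignment(cost_matrix(remaining_active, low), 1.0 - cfg.iou_gate_stage2)
    for ti, dj in m2:
        _apply_match(remaining_active[ti], low[dj], cfg)

    # stage 3: leftover high-score detections vs lost tracks (reactivation)
    leftover_high = [high[j] for j in u_det1]
    m3, _, u_det3 = solve_assignment(cost_matrix(lost, leftover_high), 1.0 - cfg.iou_gate_stage1)
    for ti, dj in m3:
        _apply_match(lost[ti], leftover_high[dj], cfg)

    # new identities from still-unmatched high detections
    for j in u_det3:
        det = leftover_high[j]
        if det.score >= cfg.tau_init:
            trk = Track(track_id=next_id, state=initiate_state(det.box), score=det.score)
            trk.history.append((det.frame, det.box, det.score))
            tracks.append(trk)
            next_id += 1

    # bookkeeping: unmatched active -> lost; stale lost -> removed
    for i in u_trk2:
        remaining_active[i].status = TrackStatus.LOST
    for t in tracks:
        if t.status is TrackStatus.LOST:
            t.frames_since_update += 1
            if t.frames_since_update > cfg.max_lost_frames:
                t.status = TrackStatus.REMOVED
    return tracks, next_id


def run_tracker(
    detection_stream: dict[int, list[Detection]] | list[list[Detection]],
    cfg: TrackerConfig | None = None,
) -> list[Track]:
    """Track a whole detection stream and return every identity created.

    ``detection_stream`` maps frame index to that frame's detections (a list
    of per-frame lists is also accepted; its positions are the frame
    indices). Frames must be presented in increasing order; frames with no
    detections may be omitted from a dict stream but still advance lost-track
    aging implicitly through the per-frame prediction loop over the full
    frame range.
    """
    if cfg is None:
        cfg = TrackerConfig()
    if isinstance(detection_stream, dict):
        frames = sorted(detection_stream)
        if frames != sorted(set(frames)):
            raise OrderingError("duplicate frame indices in detection stream")
        stream = detection_stream
        frame_range = range(frames[0], frames[-1] + 1) if frames else range(0)
    else:
        stream = {i: dets for i, dets in enumerate(detection_stream)}
        frame_range = range(len(detection_stream))

    tracks: list[Track] = []
    next_id = 1
    for frame in frame_range:
        dets = stream.get(frame, [])
        for d in dets:
            if d.frame != frame:
                raise OrderingError(
                    f"detection carries frame {d.frame} but was presented at frame {frame}"
                )
        for t in tracks:
            if t.status is not TrackStatus.REMOVED:
                t.state = kalman_predict(t.state, cfg.process_noise_scale)
        tracks, next_id = associate_frame(tracks, dets, cfg, next_id)
    return tracks
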