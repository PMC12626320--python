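"""File dialects: YOLO-txt detections, MOT tracks, behavior CSVs, config, figures.

Internal frame indices are 0-based everywhere; the MOT dialect is 1-based at
the file boundary only. Readers reject malformed input with a
:class:`~wormtrack.errors.ParseError` naming the file and line; every writer's
output is re-readable by its paired reader.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .behavior import BehaviorConfig, BehaviorEvent, BehaviorSummary, Trajectory
from .errors import ConfigError, ParseError
from .geometry import BoundingBox, Detection
from .simulate import OcclusionEpisode, SimConfig
from .tracker import Track, TrackerConfig

__all__ = [
    "read_yolo_detections",
    "write_yolo_detections",
    "write_mot_tracks",
    "read_mot_tracks",
    "write_mot_ground_truth",
    "write_events_csv",
    "behavior_series_table",
    "write_behavior_tables",
    "render_overlays",
    "RunConfig",
    "load_config",
    "save_config",
    "tracks_to_mapping",
    "truth_to_mapping",
]

_TRAILING_INT = re.compile(r"(\d+)(?=\D*$)")


# ------------------------------------------------------------- YOLO txt


def _parse_yolo_line(
    line: str, image_size: tuple[float, float], frame: int, where: str, lineno: int
) -> Detection | None:
    parts = line.split()
    if len(parts) not in (5, 6):
        raise ParseError(f"{where}:{lineno}: expected 5 or 6 fields, got {len(parts)}: {line!r}")
    try:
        class_id = int(parts[0])
        cx, cy, w, h = (float(v) for v in parts[1:5])
        score = float(parts[5]) if len(parts) == 6 else 1.0
    except ValueError as exc:
        raise ParseError(f"{where}:{lineno}: non-numeric field in {line!r}") from exc
    if class_id != 0:
        warnings.warn(f"{where}:{lineno}: skipping unknown class id {class_id}", stacklevel=2)
        return None
    iw, ih = image_size
    try:
        box = BoundingBox(cx=cx * iw, cy=cy * ih, w=w * iw, h=h * ih)
        return Detection(box=box, score=score, frame=frame, class_id=class_id)
    except ValueError as exc:
        raise ParseError(f"{where}:{lineno}: invalid geometry or score: {exc}") from exc


def read_yolo_detections(
    path: str | Path, image_size: tuple[float, float]
) -> dict[int, list[Detection]]:
    """Read normalized YOLO-txt detections into a pixel-coordinate stream.

    ``path`` is either a directory of per-frame ``*.txt`` files (frame index
    parsed from the filename's trailing integer) or a single file whose
    lines carry a leading frame column: ``frame class cx cy w h [score]``.
    """
    path = Path(path)
    stream: dict[int, list[Detection]] = {}
    if path.is_dir():
        for txt in sorted(path.glob("*.txt")):
            m = _TRAILING_INT.search(txt.stem)
            if m is None:
                raise ParseError(f"{txt}: cannot parse a frame index from the filename")
            frame = int(m.group(1))
            stream.setdefault(frame, [])
            for lineno, line in enumerate(txt.read_text().splitlines(), start=1):
                if not line.strip():
                    continue
                det = _parse_yolo_line(line, image_size, frame, str(txt), lineno)
                if det is not None:
                    stream[frame].append(det)
    else:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split(maxsplit=1)
            try:
                frame = int(parts[0])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: bad frame column in {line!r}") from exc
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: missing detection fields")
            det = _parse_yolo_line(parts[1], image_size, frame, str(path), lineno)
            if det is not None:
                stream.setdefault(frame, []).append(det)
    return stream


def write_yolo_detections(
    stream: Mapping[int, list[Detection]],
    directory: str | Path,
    image_size: tuple[float, float],
) -> list[Path]:
    """Write one normalized YOLO-txt file per frame (score column included)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iw, ih = image_size
    paths = []
    for frame in sorted(stream):
        p = directory / f"frame_{frame:06d}.txt"
        lines = [
            f"{d.class_id} {d.box.cx / iw:.9f} {d.box.cy / ih:.9f} "
            f"{d.box.w / iw:.9f} {d.box.h / ih:.9f} {d.score:.6f}"
            for d in stream[frame]
        ]
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths.append(p)
    return paths


# ------------------------------------------------------------------ MOT


def write_mot_tracks(tracks: Iterable[Track], path: str | Path) -> Path:
    """Write finished tracks as MOT lines, 1-based frames, fixed formatting.

    Line format: ``frame,id,bb_left,bb_top,w,h,score,-1,-1,-1`` with two
    decimal places on geometry and score, sorted by (frame, id).
    """
    rows = []
    for trk in tracks:
        for frame, box, score in trk.history:
            rows.append((frame + 1, trk.track_id, box.x1, box.y1, box.w, box.h, score))
    rows.sort(key=lambda r: (r[0], r[1]))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for frame, tid, x, y, w, h, score in rows:
            fh.write(f"{frame},{tid},{x:.2f},{y:.2f},{w:.2f},{h:.2f},{score:.2f},-1,-1,-1\n")
    return path


def read_mot_tracks(path: str | Path) -> dict[int, dict[int, tuple[BoundingBox, float]]]:
    """Read a MOT track file into {track_id: {frame0: (box, score)}} (0-based frames)."""
    out: dict[int, dict[int, tuple[BoundingBox, float]]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) < 7:
            raise ParseError(f"{path}:{lineno}: expected >= 7 comma-separated fields")
        try:
            frame = int(parts[0]) - 1
            tid = int(parts[1])
            x, y, w, h, score = (float(v) for v in parts[2:7])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field in {line!r}") from exc
        try:
            box = BoundingBox(cx=x + w / 2.0, cy=y + h / 2.0, w=w, h=h)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: invalid geometry: {exc}") from exc
        out.setdefault(tid, {})[frame] = (box, score)
    return out


def write_mot_ground_truth(truth, path: str | Path) -> Path:
    """Write simulator ground-truth boxes as a MOT ground-truth file."""
    rows = []
    for frame, entries in truth.boxes.items():
        for worm, box in entries:
            rows.append((frame + 1, worm + 1, box.x1, box.y1, box.w, box.h))
    rows.sort(key=lambda r: (r[0], r[1]))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for frame, wid, x, y, w, h in rows:
            fh.write(f"{frame},{wid},{x:.2f},{y:.2f},{w:.2f},{h:.2f},1,-1,-1,-1\n")
    return path


def tracks_to_mapping(tracks: Iterable[Track]) -> dict[int, dict[int, BoundingBox]]:
    """Track list -> {id: {frame: box}} for continuity evaluation."""
    return {t.track_id: {f: b for f, b, _ in t.history} for t in tracks}


def truth_to_mapping(truth) -> dict[int, dict[int, BoundingBox]]:
    """Simulator ground truth -> {worm: {frame: box}}."""
    out: dict[int, dict[int, BoundingBox]] = {}
    for frame, entries in truth.boxes.items():
        for worm, box in entries:
            out.setdefault(worm, {})[frame] = box
    return out


# -------------------------------------------------------- behavior CSVs


def behavior_series_table(
    traj: Trajectory,
    cfg: BehaviorConfig,
    orientation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame tidy series for one worm (speeds, state, bend angle, r).

    Interval-valued series (speed, state) are assigned to the later sample of
    each interval; the first row carries NaN / empty state.
    """
    from .behavior import bending_angle, classify_direction, instantaneous_speed, smooth_speed

    n = len(traj)
    speed_raw = np.full(n, np.nan)
    speed_smooth = np.full(n, np.nan)
    state = np.full(n, "", dtype="<U10")
    if n >= 2:
        v = instantaneous_speed(traj)
        speed_raw[1:] = v
        window = min(cfg.smooth_window, len(v) if len(v) % 2 == 1 else len(v) - 1)
        speed_smooth[1:] = smooth_speed(v, max(window, 1))
        state[1:] = classify_direction(traj, cfg, orientation)
    angles = [
        bending_angle(BoundingBox(cx=0.0, cy=0.0, w=w, h=h), cfg)
        for w, h in zip(traj.w, traj.h)
    ]
    return pd.DataFrame(
        {
            "worm_id": traj.track_id,
            "t": traj.t,
            "x": traj.x,
            "y": traj.y,
            "speed_raw": speed_raw,
            "speed_smooth": speed_smooth,
            "state": state,
            "bend_angle_deg": [a if a is not None else np.nan for a in angles],
            "aspect_ratio": traj.w / traj.h,
        }
    )


def write_behavior_tables(
    summaries: Iterable[BehaviorSummary],
    series: pd.DataFrame,
    events: Iterable[tuple[int, BehaviorEvent]],
    out_dir: str | Path,
    cfg: BehaviorConfig | None = None,
) -> dict[str, Path]:
    """Write the three tidy behavior CSVs plus a sidecar metadata JSON.

    ``events`` is an iterable of (worm_id, event) pairs. The metadata JSON
    records the units and every threshold used, so a results directory is
    self-describing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or BehaviorConfig()

    series_path = out_dir / "series.csv"
    series_cols = ["worm_id", "t", "x", "y", "speed_raw", "speed_smooth",
                   "state", "bend_angle_deg", "aspect_ratio"]
    (series if len(series) else pd.DataFrame(columns=series_cols))[series_cols].to_csv(
        series_path, index=False
    )

    events_path = out_dir / "events.csv"
    ev_rows = [
        {"worm_id": worm, "kind": ev.kind, "t": ev.t, "statistic": ev.statistic}
        for worm, ev in events
    ]
    pd.DataFrame(ev_rows, columns=["worm_id", "kind", "t", "statistic"]).to_csv(
        events_path, index=False
    )

    summary_path = out_dir / "summary.csv"
    sm_rows = [
        {
            "worm_id": s.track_id,
            "mean_speed": s.mean_speed,
            "roll_frequency": s.roll_frequency,
            "omega_turn_count": s.omega_turn_count,
            "fraction_forward": s.fraction_forward,
            "fraction_backward": s.fraction_backward,
            "fraction_stationary": s.fraction_stationary,
        }
        for s in summaries
    ]
    pd.DataFrame(
        sm_rows,
        columns=["worm_id", "mean_speed", "roll_frequency", "omega_turn_count",
                 "fraction_forward", "fraction_backward", "fraction_stationary"],
    ).to_csv(summary_path, index=False)

    meta_path = out_dir / "metadata.json"
    meta = {
        "units": {
            "t": "s",
            "x": "px", "y": "px",
            "speed": "px/s",
            "bend_angle_deg": "deg",
            "roll_frequency": "events/s",
        },
        "thresholds": dataclasses.asdict(cfg),
    }
    meta_path.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return {"series": series_path, "events": events_path,
            "summary": summary_path, "metadata": meta_path}


# ---------------------------------------------------------------- plots


def render_overlays(
    trajectories: Mapping[int, Trajectory],
    events: Iterable[tuple[int, BehaviorEvent]],
    out_dir: str | Path,
    make_3d: bool = False,
) -> dict[str, Path]:
    """Render trajectory/event overview figures (presentation only).

    Produces a speed-colored trajectory plot with event markers (red circles
    for omega turns, blue crosses for rolls), per-event-type 2D spatial
    density heatmaps, and optionally an x-y-time 3D scatter of events.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .behavior import instantaneous_speed

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events = list(events)
    out: dict[str, Path] = {}

    def _event_xy(kind: str) -> tuple[list[float], list[float], list[float]]:
        xs, ys, ts = [], [], []
        for worm, ev in events:
            if ev.kind != kind or worm not in trajectories:
                continue
            traj = trajectories[worm]
            i = int(np.argmin(np.abs(traj.t - ev.t)))
            xs.append(traj.x[i]); ys.append(traj.y[i]); ts.append(ev.t)
        return xs, ys, ts

    fig, ax = plt.subplots(figsize=(7, 6))
    for traj in trajectories.values():
        if len(traj) >= 2:
            v = instantaneous_speed(traj)
            sc = ax.scatter(traj.x[1:], traj.y[1:], c=v, s=2, cmap="viridis")
        else:
            ax.plot(traj.x, traj.y, ".", color="gray")
    ox, oy, _ = _event_xy("omega_turn")
    rx, ry, _ = _event_xy("roll")
    ax.plot(ox, oy, "o", mfc="none", mec="red", ms=10, label="omega turn")
    ax.plot(rx, ry, "x", color="blue", ms=8, label="roll")
    if len(trajectories) and any(len(t) >= 2 for t in trajectories.values()):
        fig.colorbar(sc, ax=ax, label="speed (px/s)")
    ax.invert_yaxis()
    ax.set_xlabel("x (px)"); ax.set_ylabel("y (px)")
    ax.legend(loc="best")
    p = out_dir / "trajectories.png"
    fig.savefig(p, dpi=110); plt.close(fig)
    out["trajectories"] = p

    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    for ax2, kind, cmap in ((axes[0], "omega_turn", "Reds"), (axes[1], "roll", "Blues")):
        xs, ys, _ = _event_xy(kind)
        if xs:
            ax2.hist2d(xs, ys, bins=20, cmap=cmap)
        ax2.set_title(f"{kind} density ({len(xs)} events)")
        ax2.invert_yaxis()
    p = out_dir / "event_heatmaps.png"
    fig.savefig(p, dpi=110); plt.close(fig)
    out["heatmaps"] = p

    if make_3d:
        fig = plt.figure(figsize=(7, 6))
        ax3 = fig.add_subplot(projection="3d")
        for kind, color in (("omega_turn", "red"), ("roll", "blue")):
            xs, ys, ts = _event_xy(kind)
            if xs:
                ax3.scatter(xs, ys, ts, color=color, label=kind)
        ax3.set_xlabel("x (px)"); ax3.set_ylabel("y (px)"); ax3.set_zlabel("t (s)")
        if events:
            ax3.legend()
        p = out_dir / "events_3d.png"
        fig.savefig(p, dpi=110); plt.close(fig)
        out["events_3d"] = p
    return out


# --------------------------------------------------------------- config


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration: tracker, behavior, simulator, I/O."""

    tracker: TrackerConfig = dataclasses.field(default_factory=TrackerConfig)
    behavior: BehaviorConfig = dataclasses.field(default_factory=BehaviorConfig)
    sim: SimConfig | None = None
    fps: float = 25.0
    image_size: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.image_size is not None and min(self.image_size) <= 0:
            raise ConfigError("image dimensions must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; absent sections fall back to defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        tracker = TrackerConfig(**raw.get("tracker", {}))
        behavior = BehaviorConfig(**raw.get("behavior", {}))
        sim = None
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "arena" in sim_raw:
                sim_raw["arena"] = tuple(sim_raw["arena"])
            if "init_positions" in sim_raw and sim_raw["init_positions"] is not None:
                sim_raw["init_positions"] = tuple(tuple(p) for p in sim_raw["init_positions"])
            if "occlusion_episodes" in sim_raw:
                sim_raw["occlusion_episodes"] = tuple(
                    OcclusionEpisode(**ep) for ep in sim_raw["occlusion_episodes"]
                )
            sim = SimConfig(**sim_raw)
        io_raw = raw.get("io", {})
        image_size = io_raw.get("image_size")
        if image_size is not None:
            image_size = tuple(float(v) for v in image_size)
        return RunConfig(
            tracker=tracker,
            behavior=behavior,
            sim=sim,
            fps=float(io_raw.get("fps", raw.get("fps", 25.0))),
            image_size=image_size,
        )
    except TypeError as exc:
        raise ConfigError(f"{path}: unknown or invalid config key: {exc}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Echo the effective configuration to YAML (runs reproducible from artifacts)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "tracker": dataclasses.asdict(cfg.tracker),
        "behavior": dataclasses.asdict(cfg.behavior),
        "sim": dataclasses.asdict(cfg.sim) if cfg.sim is not None else None,
        "io": {"fps": cfg.fps, "image_size": list(cfg.image_size) if cfg.image_size else None},
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
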