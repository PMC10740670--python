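"""Trajectories, gap filling, segmentation, and per-segment kinematics.

A trajectory is one animal's full 2-D coordinate time series as produced by
video-tracking software (one row per video frame, pixel units, camera
convention: origin top-left, y increasing downward).  Tracking dropouts are
represented as NaN rows.  The unit of all downstream analysis is the
:class:`TrackSegment`: a fixed-duration, gap-free window of a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ArenaGeometry",
    "ClassLabel",
    "Trajectory",
    "TrackSegment",
    "load_trajectory",
    "fill_gaps",
    "segment_trajectory",
    "step_speeds",
    "average_speed",
    "segment_index",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular well geometry in pixel units."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError(f"arena radius must be > 0, got {self.radius}")

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the square circumscribing the well."""
        cx, cy = self.center
        r = self.radius
        return (cx - r, cy - r, cx + r, cy + r)


@dataclass(frozen=True, order=True)
class ClassLabel:
    """Exposure condition of one animal.

    ``concentration`` is percent v/v; controls have concentration 0 and all
    control animals are merged into the single ``control`` class.
    """

    kind: str  # "control" or "drug"
    concentration: float = 0.0
    drug_name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("control", "drug"):
            raise ValidationError(f"label kind must be 'control' or 'drug', got {self.kind!r}")
        if self.concentration < 0:
            raise ValidationError("concentration must be >= 0")
        if (self.kind == "control") != (self.concentration == 0):
            raise ValidationError("control labels must have concentration 0 and vice versa")

    @property
    def name(self) -> str:
        if self.kind == "control":
            return "control"
        return f"{self.drug_name or 'drug'}_{self.concentration:g}"

    @staticmethod
    def control() -> "ClassLabel":
        return ClassLabel(kind="control")

    @staticmethod
    def drug(drug_name: str, concentration: float) -> "ClassLabel":
        if concentration == 0:
            return ClassLabel.control()
        return ClassLabel(kind="drug", concentration=concentration, drug_name=drug_name)


@dataclass
class Trajectory:
    """One animal's coordinate time series; missing frames are NaN."""

    fish_id: str
    label: ClassLabel
    fps: float
    positions: np.ndarray  # (n_frames, 2) float64, NaN rows = missing
    arena: ArenaGeometry

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 2)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_seconds(self) -> float:
        return len(self) / self.fps

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.positions).any(axis=1).sum())


@dataclass
class TrackSegment:
    """A gap-free, fixed-duration window of a trajectory.

    This is the classification unit: ``window_seconds`` of consecutive
    coordinates (``round(window_seconds * fps)`` points).
    """

    fish_id: str
    label: ClassLabel
    start_time: float  # seconds from recording start
    coords: np.ndarray  # (n_points, 2), no NaN
    window_seconds: float
    fps: float
    arena: ArenaGeometry
    segment_id: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 2)
        expected = int(round(self.window_seconds * self.fps))
        if self.coords.shape[0] != expected:
            raise ValidationError(
                f"segment must hold round(window_seconds*fps)={expected} points, "
                f"got {self.coords.shape[0]}"
            )
        if np.isnan(self.coords).any():
            raise ValidationError("segment coordinates must be gap-free")

    @property
    def ref(self) -> tuple[str, int]:
        return (self.fish_id, self.segment_id)


def load_trajectory(
    path,
    fps: float,
    arena: ArenaGeometry,
    label: ClassLabel,
    fish_id: str | None = None,
) -> Trajectory:
    """Read an idTracker-style per-fish CSV (columns frame, x, y).

    Returns a trajectory with one entry per frame index from 0 to the last
    recorded frame; frames absent from the file, or with NaN coordinates,
    are marked missing.  Frame indices must be strictly increasing.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - message path
        raise ValidationError(f"malformed trajectory CSV {path}: {exc}") from exc
    missing_cols = {"frame", "x", "y"} - set(df.columns)
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {sorted(missing_cols)}")
    frames = df["frame"].to_numpy()
    if np.isnan(frames).any():
        bad = int(np.flatnonzero(np.isnan(frames))[0]) + 2  # 1-based + header
        raise ValidationError(f"{path}: non-numeric frame index at line {bad}")
    if len(frames) and not np.all(np.diff(frames) > 0):
        bad = int(np.flatnonzero(np.diff(frames) <= 0)[0]) + 3
        raise ValidationError(f"{path}: frame indices not strictly increasing at line {bad}")
    n = int(frames[-1]) + 1 if len(frames) else 0
    positions = np.full((n, 2), np.nan)
    idx = frames.astype(int)
    positions[idx, 0] = df["x"].to_numpy(dtype=np.float64)
    positions[idx, 1] = df["y"].to_numpy(dtype=np.float64)
    return Trajectory(
        fish_id=fish_id if fish_id is not None else str(path),
        label=label,
        fps=fps,
        positions=positions,
        arena=arena,
    )


def fill_gaps(traj: Trajectory, max_gap: int = 12) -> Trajectory:
    """Linearly interpolate runs of at most ``max_gap`` missing frames.

    Longer runs, and missing frames at the start or end of the recording
    (which have no flanking observations), are left missing; segmentation
    later drops any window that still overlaps a gap.  The default of 12
    frames is about half a second at 25 fps — the scale of typical tracker
    dropouts.
    """
    pos = traj.positions.copy()
    missing = np.isnan(pos).any(axis=1)
    if not missing.any():
        return Trajectory(traj.fish_id, traj.label, traj.fps, pos, traj.arena)
    n = len(pos)
    # identify runs of consecutive missing frames
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        run_len = j - i
        if run_len <= max_gap and i > 0 and j < n:
            left, right = pos[i - 1], pos[j]
            t = np.arange(1, run_len + 1) / (run_len + 1)
            pos[i:j] = left + t[:, None] * (right - left)
        i = j
    return Trajectory(traj.fish_id, traj.label, traj.fps, pos, traj.arena)


def segment_trajectory(
    traj: Trajectory,
    window_seconds: float = 30.0,
    *,
    return_dropped: bool = False,
):
    """Clip a trajectory into consecutive non-overlapping windows.

    Windows are half-open ``[t, t+w)`` starting at time 0; the final partial
    window is discarded, so a gap-free recording yields
    ``floor(duration / window_seconds)`` segments (a 90-min recording with
    30-s windows gives 180).  Windows still containing missing coordinates
    are dropped; set ``return_dropped`` to also get their indices.
    """
    if not window_seconds > 0:
        raise ValidationError(f"window_seconds must be > 0, got {window_seconds}")
    w = int(round(window_seconds * traj.fps))
    n_windows = len(traj) // w if w > 0 else 0
    segments: list[TrackSegment] = []
    dropped: list[int] = []
    for i in range(n_windows):
        coords = traj.positions[i * w : (i + 1) * w]
        if np.isnan(coords).any():
            dropped.append(i)
            continue
        segments.append(
            TrackSegment(
                fish_id=traj.fish_id,
                label=traj.label,
                start_time=i * window_seconds,
                coords=coords,
                window_seconds=window_seconds,
                fps=traj.fps,
                arena=traj.arena,
                segment_id=i,
            )
        )
    if return_dropped:
        return segments, dropped
    return segments


def step_speeds(seg: TrackSegment) -> np.ndarray:
    """Instantaneous speed of every step, in pixels/second.

    ``speed[i]`` is the Euclidean distance between points i and i+1 times
    the frame rate; the result has one entry fewer than the segment.
    """
    deltas = np.diff(seg.coords, axis=0)
    return np.hypot(deltas[:, 0], deltas[:, 1]) * seg.fps


def average_speed(seg: TrackSegment) -> float:
    """Mean step speed over the segment (px/s); 0 for a stationary segment."""
    speeds = step_speeds(seg)
    return float(speeds.mean()) if speeds.size else 0.0


def segment_index(segments: list[TrackSegment]) -> pd.DataFrame:
    """Tabulate segments (fish_id, segment_id, start_time, label, mean_speed)."""
    rows = [
        {
            "fish_id": s.fish_id,
            "segment_id": s.segment_id,
            "start_time": s.start_time,
            "label": s.label.name,
            "concentration": s.label.concentration,
            "mean_speed": average_speed(s),
        }
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=["fish_id", "segment_id", "start_time", "label", "concentration", "mean_speed"],
    )
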