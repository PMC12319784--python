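"""Pose-telemetry handling: key-point tracks -> normalised speed observations.

Key-point tracks come from a video pose estimator (OpenPose body-25 style):
per frame, an (x, y) pixel position and a confidence score for each of 25
body landmarks.  Downstream behavioural segmentation consumes per-frame
key-point *speeds* (pixels/frame), z-scored per key-point within each
recording session.  This module reads the raw tracks, repairs detector
drop-outs, differentiates to speed, normalises and aligns sessions of
differing frame rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BODY25_KEYPOINTS",
    "KeypointSeries",
    "SpeedMatrix",
    "load_keypoints",
    "interpolate_missing",
    "to_speed",
    "znormalize",
    "resample_rate",
    "concatenate_sessions",
]

#: Landmark names of the OpenPose body-25 model, in output order.
BODY25_KEYPOINTS = [
    "nose", "neck",
    "r_shoulder", "r_elbow", "r_wrist",
    "l_shoulder", "l_elbow", "l_wrist",
    "mid_hip",
    "r_hip", "r_knee", "r_ankle",
    "l_hip", "l_knee", "l_ankle",
    "r_eye", "l_eye", "r_ear", "l_ear",
    "l_big_toe", "l_small_toe", "l_heel",
    "r_big_toe", "r_small_toe", "r_heel",
]


class TelemetryFormatError(ValueError):
    """Raised when a key-point file does not parse under the named dialect."""


@dataclass
class KeypointSeries:
    """Per-frame key-point positions and detector confidences.

    Missing observations (confidence 0 or absent record) are stored as NaN
    positions until :func:`interpolate_missing` repairs them.
    """

    positions: np.ndarray          # (frames, keypoints, 2) pixels; NaN = missing
    confidence: np.ndarray         # (frames, keypoints) in [0, 1]
    frame_rate: float              # frames / s
    keypoint_names: list[str] = field(default_factory=lambda: list(BODY25_KEYPOINTS))
    session_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (frames, keypoints, 2)")
        if self.confidence.shape != self.positions.shape[:2]:
            raise ValueError("confidence shape must match positions")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if np.nanmin(self.confidence, initial=0.0) < 0 or np.nanmax(self.confidence, initial=0.0) > 1:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.positions.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean (frames, keypoints) mask of missing observations."""
        return np.isnan(self.positions).any(axis=2)


@dataclass
class SpeedMatrix:
    """Frames x key-points speed observations.

    Units are pixels/frame before normalisation and z-units after.
    ``session_boundaries`` holds the cumulative frame counts at session
    joins (empty for a single session), so per-session statistics remain
    recoverable after concatenation.
    """

    values: np.ndarray             # (frames, keypoints)
    frame_rate: float
    normalised: bool = False
    session_boundaries: list[int] = field(default_factory=list)
    keypoint_names: list[str] = field(default_factory=lambda: list(BODY25_KEYPOINTS))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames, keypoints)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.values.shape[1]

    def segments(self) -> list[tuple[int, int]]:
        """Half-open (start, stop) frame ranges of each session."""
        edges = [0, *self.session_boundaries, self.n_frames]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


# ---------------------------------------------------------------------------
# reading


def _series_from_records(df: pd.DataFrame, frame_rate: float, session_id: str,
                         n_keypoints: int | None = None) -> KeypointSeries:
    if len(df) == 0:
        raise ValueError("empty input: no frames found")
    n_frames = int(df["frame"].max()) + 1
    if n_keypoints is None:
        n_keypoints = int(df["keypoint"].max()) + 1
    positions = np.full((n_frames, n_keypoints, 2), np.nan)
    confidence = np.zeros((n_frames, n_keypoints))
    fi = df["frame"].to_numpy(dtype=int)
    ki = df["keypoint"].to_numpy(dtype=int)
    conf = df["confidence"].to_numpy(dtype=float)
    positions[fi, ki, 0] = df["x"].to_numpy(dtype=float)
    positions[fi, ki, 1] = df["y"].to_numpy(dtype=float)
    confidence[fi, ki] = conf
    # confidence 0 (or absent record) marks an undetected part
    positions[confidence == 0] = np.nan
    names = (list(BODY25_KEYPOINTS) if n_keypoints == 25
             else [f"kp{j}" for j in range(n_keypoints)])
    return KeypointSeries(positions, confidence, frame_rate, names, session_id)


def _load_csv(path: Path, frame_rate: float) -> KeypointSeries:
    df = pd.read_csv(path)
    required = {"frame", "keypoint", "x", "y", "confidence"}
    if not required.issubset(df.columns):
        raise TelemetryFormatError(
            f"{path}: CSV dialect requires columns {sorted(required)}, "
            f"got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"empty input: no frames in {path}")
    bad = df[~np.isfinite(df[["x", "y", "confidence"]]).all(axis=1)]
    if len(bad):
        raise TelemetryFormatError(
            f"{path}: non-finite record at row {bad.index[0]}: "
            f"{bad.iloc[0].to_dict()}")
    return _series_from_records(df, frame_rate, path.stem)


def _best_person(people: list[dict]) -> np.ndarray | None:
    """Pick the detection with the highest mean confidence; (25, 3) array."""
    best, best_conf = None, -np.inf
    for person in people:
        flat = np.asarray(person["pose_keypoints_2d"], dtype=float)
        if flat.size % 3 != 0:
            raise TelemetryFormatError(
                "pose_keypoints_2d length must be a multiple of 3")
        kp = flat.reshape(-1, 3)
        mc = kp[:, 2].mean()
        if mc > best_conf:
            best, best_conf = kp, mc
    return best


def _load_openpose_json(path: Path, frame_rate: float) -> KeypointSeries:
    """OpenPose output: a directory of per-frame JSON files, or one JSON
    array of frame objects.  Each frame object has a ``people`` list whose
    entries carry flat ``pose_keypoints_2d`` = [x0, y0, c0, x1, y1, c1, ...].
    Multi-person frames are resolved to the person with the highest mean
    confidence."""
    if path.is_dir():
        files = sorted(path.glob("*.json"))
        if not files:
            raise ValueError(f"empty input: no JSON frames in {path}")
        frames = []
        for f in files:
            try:
                frames.append(json.loads(f.read_text()))
            except json.JSONDecodeError as e:
                raise TelemetryFormatError(f"{f}: invalid JSON ({e})") from e
    else:
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise TelemetryFormatError(f"{path}: invalid JSON ({e})") from e
        frames = obj if isinstance(obj, list) else [obj]
    if not frames:
        raise ValueError(f"empty input: no frames in {path}")

    kps = []
    for i, frame in enumerate(frames):
        if "people" not in frame:
            raise TelemetryFormatError(
                f"{path}: frame {i} has no 'people' field")
        kps.append(_best_person(frame["people"]))
    n_kp = next((k.shape[0] for k in kps if k is not None), 25)
    positions = np.full((len(kps), n_kp, 2), np.nan)
    confidence = np.zeros((len(kps), n_kp))
    for i, kp in enumerate(kps):
        if kp is None:
            continue
        positions[i] = kp[:, :2]
        confidence[i] = kp[:, 2]
    positions[confidence == 0] = np.nan
    names = (list(BODY25_KEYPOINTS) if n_kp == 25
             else [f"kp{j}" for j in range(n_kp)])
    return KeypointSeries(positions, confidence, frame_rate, names, path.stem)


def load_keypoints(path: str | Path, dialect: str = "csv",
                   frame_rate: float = 30.0) -> KeypointSeries:
    """Read key-point tracks from disk.

    Parameters
    ----------
    path
        CSV file (``frame,keypoint,x,y,confidence`` header, 0-based frame
        index) or OpenPose JSON file/directory depending on ``dialect``.
    dialect
        ``"csv"`` or ``"openpose_json"``.
    frame_rate
        Video frame rate in frames/s (not stored in either dialect).

    Observations with confidence exactly 0, or absent from the file, are
    marked missing (NaN position).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _load_csv(path, frame_rate)
    if dialect == "openpose_json":
        return _load_openpose_json(path, frame_rate)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# repair / transform


def interpolate_missing(series: KeypointSeries) -> KeypointSeries:
    """Fill missing observations by linear interpolation over frame index.

    Interior gaps are interpolated per coordinate; gaps at either edge take
    the nearest observed value.  A key-point never observed at all is an
    error (there is nothing to interpolate from).
    """
    pos = series.positions.copy()
    t = np.arange(series.n_frames, dtype=float)
    for j in range(series.n_keypoints):
        ok = ~np.isnan(pos[:, j]).any(axis=1)
        if not ok.any():
            raise ValueError(
                f"key-point {series.keypoint_names[j]!r} is never observed")
        if ok.all():
            continue
        for c in range(2):
            # np.interp clamps to the edge values outside the observed range
            pos[:, j, c] = np.interp(t, t[ok], pos[ok, j, c])
    return replace(series, positions=pos)


def to_speed(series: KeypointSeries) -> SpeedMatrix:
    """Differentiate positions to per-frame speeds (pixels/frame).

    Speed at frame t is the Euclidean step length between frames t-1 and t;
    frame 0 is padded with 0 so speeds stay index-aligned with video frames.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to compute speed")
    if series.missing.any():
        raise ValueError("series contains missing data; interpolate first")
    step = np.diff(series.positions, axis=0)
    speed = np.linalg.norm(step, axis=2)
    speed = np.vstack([np.zeros((1, series.n_keypoints)), speed])
    return SpeedMatrix(speed, series.frame_rate, normalised=False,
                       keypoint_names=list(series.keypoint_names))


def znormalize(speeds: SpeedMatrix) -> SpeedMatrix:
    """Z-score each key-point column within each session segment.

    Constant columns cannot be scaled; they are mapped to all-zero with a
    warning so a frozen detector does not poison the observation model.
    """
    if speeds.normalised:
        warnings.warn("speeds already normalised; renormalising is a no-op "
                      "up to numerical tolerance")
    out = speeds.values.copy()
    for start, stop in speeds.segments():
        seg = out[start:stop]
        mu = seg.mean(axis=0)
        sd = seg.std(axis=0, ddof=0)
        const = np.ptp(seg, axis=0) == 0
        if const.any():
            names = [speeds.keypoint_names[j] for j in np.flatnonzero(const)]
            warnings.warn(f"constant speed column(s) {names} set to zero")
            sd = np.where(const, 1.0, sd)
        seg = (seg - mu) / sd
        seg[:, const] = 0.0
        out[start:stop] = seg
    return replace(speeds, values=out, normalised=True)


def resample_rate(speeds: SpeedMatrix, target_rate: float) -> SpeedMatrix:
    """Linearly interpolate the speed matrix onto a new frame-rate time base.

    The output covers the same duration (within one frame period); used to
    bring 50 Hz sessions onto the common 30 Hz video clock.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if target_rate == speeds.frame_rate:
        return replace(speeds, values=speeds.values.copy())
    if speeds.session_boundaries:
        raise ValueError("resample before concatenating sessions")
    t_src = np.arange(speeds.n_frames) / speeds.frame_rate
    n_out = int(np.floor(t_src[-1] * target_rate)) + 1
    t_tgt = np.arange(n_out) / target_rate
    out = np.empty((n_out, speeds.n_keypoints))
    for j in range(speeds.n_keypoints):
        out[:, j] = np.interp(t_tgt, t_src, speeds.values[:, j])
    return replace(speeds, values=out, frame_rate=float(target_rate))


def concatenate_sessions(sessions: list[SpeedMatrix]) -> SpeedMatrix:
    """Concatenate per-session (already normalised) speed matrices in time."""
    if not sessions:
        raise ValueError("no sessions to concatenate")
    first = sessions[0]
    for s in sessions[1:]:
        if s.keypoint_names != first.keypoint_names:
            raise ValueError("mismatched key-point sets across sessions")
        if s.frame_rate != first.frame_rate:
            raise ValueError("mismatched frame rates across sessions")
        if s.normalised != first.normalised:
            raise ValueError("mix of normalised and unnormalised sessions")
    values = np.vstack([s.values for s in sessions])
    boundaries = list(np.cumsum([s.n_frames for s in sessions])[:-1])
    return SpeedMatrix(values, first.frame_rate, first.normalised,
                       boundaries, list(first.keypoint_names))
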