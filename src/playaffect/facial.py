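"""Facial-activity features F1-F7 from 68-point landmark tracks.

Landmarks follow the iBUG-68 layout (0-based): jaw 0-16, right brow 17-21,
left brow 22-26, nose 27-35, right eye 36-41, left eye 42-47, outer lip
48-59, inner lip 60-67.  Each feature monitors a facial muscle or behaviour
known to respond to emotional state:

F1  mouth outer     perimeter of the outer-lip contour (zygomatic)
F2  mouth corner    distance between mouth corners 48-54 (zygomatic)
F3  eye area        summed shoelace area of the two eye polygons (orbicularis
                    oculi; drops to ~0 during a blink)
F4  eyebrow         distance between inner brow points 21-22 (corrugator
                    contraction pulls them together)
F5  face area       convex-hull area of all 68 points (grows as the face
                    approaches the camera)
F6  face motion     trailing 1 s path length of the nose tip (landmark 30)
F7  facial COM      per-frame displacement of the centroid of all landmarks

Per-window aggregation: mean for the slow features F1, F2, F5; population
standard deviation for the fast-changing F3, F4, F6, F7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .exceptions import InvalidInputError
from .segmentation import AnalysisWindow

N_LANDMARKS = 68
NOSE_TIP = 30
OUTER_LIP = slice(48, 60)
RIGHT_EYE = slice(36, 42)
LEFT_EYE = slice(42, 48)
MOUTH_CORNERS = (48, 54)
INNER_BROWS = (21, 22)

FACIAL_FEATURES = ("F1", "F2", "F3", "F4", "F5", "F6", "F7")
#: aggregation rule per feature: slow features by mean, fast ones by std
MEAN_AGGREGATED = frozenset({"F1", "F2", "F5"})
STD_AGGREGATED = frozenset({"F3", "F4", "F6", "F7"})


def _as_frames(points: np.ndarray) -> np.ndarray:
    """Validate and return landmarks shaped (n_frames, 68, 2)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2:
        pts = pts[None]
    if pts.ndim != 3 or pts.shape[1:] != (N_LANDMARKS, 2):
        raise InvalidInputError(
            f"expected (..., {N_LANDMARKS}, 2) landmark array, got shape {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("landmark coordinates must be finite")
    return pts


@dataclass
class LandmarkTrack:
    """Uniformly sampled 68-point landmark positions of one recording.

    Attributes
    ----------
    fps : float
        Frame rate (> 0); frames are spaced 1/fps apart.
    points : ndarray, shape (n_frames, 68, 2)
        Pixel coordinates per frame.
    t0 : float
        Time of the first frame on the session clock.
    confidence : ndarray or None
        Optional per-frame detector confidence in [0, 1].
    """

    fps: float
    points: np.ndarray
    t0: float = 0.0
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidInputError(f"fps must be > 0: {self.fps}")
        if self.t0 < 0:
            raise InvalidInputError("track start time must be >= 0")
        self.points = _as_frames(self.points)
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (len(self.points),):
                raise InvalidInputError("confidence must have one value per frame")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.points)) / self.fps

    def frame_indices(self, window: AnalysisWindow) -> np.ndarray:
        """Indices of frames with t in [window.start_s, window.end_s)."""
        t = self.t
        lo = int(np.searchsorted(t, window.start_s - 1e-9, side="left"))
        hi = int(np.searchsorted(t, window.end_s - 1e-9, side="left"))
        return np.arange(lo, hi)


# ---------------------------------------------------------------- per-frame ops

def mouth_outer(points: np.ndarray) -> np.ndarray | float:
    """F1: closed perimeter of the outer-lip contour (points 48-59), pixels."""
    pts = _as_frames(points)
    lip = pts[:, OUTER_LIP]
    seg = np.linalg.norm(np.roll(lip, -1, axis=1) - lip, axis=-1)
    out = seg.sum(axis=-1)
    return out if np.ndim(points) == 3 else float(out[0])


def mouth_corner(points: np.ndarray) -> np.ndarray | float:
    """F2: Euclidean distance between the mouth corners 48 and 54, pixels."""
    pts = _as_frames(points)
    out = np.linalg.norm(pts[:, MOUTH_CORNERS[0]] - pts[:, MOUTH_CORNERS[1]], axis=-1)
    return out if np.ndim(points) == 3 else float(out[0])


def _shoelace(poly: np.ndarray) -> np.ndarray:
    """Absolute polygon area, vectorized over leading axes; poly (..., k, 2)."""
    x, y = poly[..., 0], poly[..., 1]
    xn, yn = np.roll(x, -1, axis=-1), np.roll(y, -1, axis=-1)
    return 0.5 * np.abs(np.sum(x * yn - xn * y, axis=-1))


def eye_area(points: np.ndarray) -> np.ndarray | float:
    """F3: summed shoelace area of the two 6-point eye contours, pixels^2."""
    pts = _as_frames(points)
    out = _shoelace(pts[:, RIGHT_EYE]) + _shoelace(pts[:, LEFT_EYE])
    return out if np.ndim(points) == 3 else float(out[0])


def eyebrow_activity(points: np.ndarray) -> np.ndarray | float:
    """F4: distance between the inner eyebrow landmarks 21 and 22, pixels."""
    pts = _as_frames(points)
    out = np.linalg.norm(pts[:, INNER_BROWS[0]] - pts[:, INNER_BROWS[1]], axis=-1)
    return out if np.ndim(points) == 3 else float(out[0])


def face_area(points: np.ndarray) -> np.ndarray | float:
    """F5: convex-hull area of all 68 landmarks, pixels^2 (0 if degenerate)."""
    pts = _as_frames(points)
    out = np.empty(len(pts))
    for i, frame in enumerate(pts):
        try:
            out[i] = ConvexHull(frame).volume  # 2-D: "volume" is the area
        except QhullError:
            out[i] = 0.0
    return out if np.ndim(points) == 3 else float(out[0])


def face_motion(track: LandmarkTrack, i: int | None = None) -> np.ndarray | float:
    """F6: trailing 1 s sum (inclusive of frame i) of nose-tip displacements.

    Frames with no predecessor inside the trailing second contribute 0.
    With ``i`` omitted the whole per-frame series is returned.
    """
    nose = track.points[:, NOSE_TIP]
    step = np.linalg.norm(np.diff(nose, axis=0), axis=-1)
    disp = np.concatenate([[0.0], step])
    w = int(round(track.fps))
    kernel_sum = np.cumsum(disp)
    series = kernel_sum.copy()
    series[w:] = kernel_sum[w:] - kernel_sum[:-w]
    if i is None:
        return series
    if not 0 <= i < len(track):
        raise InvalidInputError(f"frame index {i} outside track of {len(track)} frames")
    return float(series[i])


def facial_com(track: LandmarkTrack, i: int | None = None) -> np.ndarray | float:
    """F7: displacement of the 68-point centroid between frames i-1 and i."""
    centroid = track.points.mean(axis=1)
    series = np.concatenate([[0.0], np.linalg.norm(np.diff(centroid, axis=0), axis=-1)])
    if i is None:
        return series
    if not 0 <= i < len(track):
        raise InvalidInputError(f"frame index {i} outside track of {len(track)} frames")
    return float(series[i])


# -------------------------------------------------------------- series / windows

def frame_features(track: LandmarkTrack) -> pd.DataFrame:
    """Per-frame values of F1-F7 for a whole track, indexed by frame time."""
    pts = track.points
    data = {
        "F1": mouth_outer(pts),
        "F2": mouth_corner(pts),
        "F3": eye_area(pts),
        "F4": eyebrow_activity(pts),
        "F5": face_area(pts),
        "F6": face_motion(track),
        "F7": facial_com(track),
    }
    return pd.DataFrame(data, index=pd.Index(track.t, name="t"))


def aggregate_window(
    series: np.ndarray | pd.Series,
    feature_id: str,
    window: AnalysisWindow,
    fps: float,
    t0: float = 0.0,
) -> float:
    """Aggregate one per-frame feature series over one analysis window.

    Mean for F1/F2/F5, population (n-denominator) standard deviation for
    F3/F4/F6/F7.  The window must be fully covered by the series.
    """
    if feature_id not in FACIAL_FEATURES:
        raise InvalidInputError(f"unknown facial feature: {feature_id}")
    values = np.asarray(series, dtype=float)
    t = t0 + np.arange(len(values)) / fps
    lo = int(np.searchsorted(t, window.start_s - 1e-9, side="left"))
    hi = int(np.searchsorted(t, window.end_s - 1e-9, side="left"))
    if lo >= hi:
        raise InvalidInputError(f"window {window} not covered by series")
    if window.start_s < t0 - 1e-9 or window.end_s > t0 + len(values) / fps + 1e-9:
        raise InvalidInputError(f"window {window} extends past the series")
    chunk = values[lo:hi]
    if feature_id in MEAN_AGGREGATED:
        return float(chunk.mean())
    return float(chunk.std())  # ddof=0: population convention


def window_features(
    track: LandmarkTrack,
    windows: Sequence[AnalysisWindow],
    features: Sequence[str] = FACIAL_FEATURES,
) -> pd.DataFrame:
    """Aggregated F1-F7 values for a sequence of windows.

    Returns a DataFrame with ``window_start_s`` plus one column per feature.
    """
    per_frame = frame_features(track)
    rows = []
    for w in windows:
        idx = track.frame_indices(w)
        if len(idx) == 0 or w.start_s < track.t0 - 1e-9 or w.end_s > track.t0 + len(track) / track.fps + 1e-9:
            raise InvalidInputError(f"window {w} extends past the track")
        chunk = per_frame.iloc[idx]
        row: dict[str, float] = {"window_start_s": w.start_s}
        for f in features:
            col = chunk[f].to_numpy()
            row[f] = float(col.mean()) if f in MEAN_AGGREGATED else float(col.std())
        rows.append(row)
    return pd.DataFrame(rows, columns=["window_start_s", *features])
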