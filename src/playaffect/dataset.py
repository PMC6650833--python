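"""Dataset assembly: labeled training samples from calibration segments and
the independent test set from evaluation levels.

Training samples come from the moving-window features of the H0 (boredom)
and H1 (stress) thirds of each calibration game — one sample per 1 s window
step, class-balanced per game by construction since |H0| = |H1|.

Test samples come from evaluation levels chosen by the subject's own
self-reports.  Each 5-point Likert pair is turned into antisymmetric scores

    stress_ij  = rstress_ij  - rboredom_ij
    boredom_ij = rboredom_ij - rstress_ij

the two levels with the highest stress score and the two with the highest
boredom score are selected, any selected level whose relevant score is < 1
is excluded as inconclusive, and features are sampled every 5 seconds
(windows [t-15, t) ending at t = 15, 20, 25, ... within the level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .facial import FACIAL_FEATURES, LandmarkTrack, window_features
from .rppg import RGBTrace, RppgConfig, hr_feature_series, sensor_hr_series
from .segmentation import AnalysisWindow, GameSegment, enumerate_windows

log = logging.getLogger("playaffect.dataset")

ALL_FEATURES = ("F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "F9")

#: Study-1 test presets plus the Study-2 deployment set (F1-F8)
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "MULTI_R": ("F1", "F2", "F3", "F4", "F5", "F6", "F8"),
    "MULTI_G": ("F1", "F2", "F3", "F4", "F5", "F6", "F9"),
    "FACE": ("F1", "F2", "F3", "F4", "F5", "F6"),
    "HR_R": ("F8",),
    "HR_G": ("F9",),
    "STUDY2": ("F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8"),
}

LABELS = ("boredom", "stress")
SAMPLE_COLUMNS = ("label", "subject", "source", "window_start_s")


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named subset of {F1..F9} used by one classification test."""

    test_id: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.features) - set(ALL_FEATURES)
        if unknown or not self.features:
            raise InvalidInputError(f"bad feature set {self.features}")

    @classmethod
    def preset(cls, name: str) -> "FeatureSetSpec":
        try:
            return cls(name, FEATURE_SETS[name])
        except KeyError:
            raise InvalidInputError(
                f"unknown preset {name!r}; choose from {sorted(FEATURE_SETS)}"
            ) from None


def session_window_features(
    windows: Sequence[AnalysisWindow],
    features: Sequence[str],
    track: LandmarkTrack | None = None,
    trace: RGBTrace | None = None,
    sensor_t: np.ndarray | None = None,
    sensor_bpm: np.ndarray | None = None,
    rppg_cfg: RppgConfig | None = None,
) -> pd.DataFrame:
    """Per-window values of the requested features for one recording.

    Facial features need ``track``, F8 needs ``trace``, F9 needs the sensor
    series.  Returns ``window_start_s`` plus one column per feature; rows
    may hold NaN (e.g. a leading run of windows with no HR estimate).
    """
    windows = list(windows)
    parts: list[pd.DataFrame] = []
    facial = [f for f in features if f in FACIAL_FEATURES]
    if facial:
        if track is None:
            raise InvalidInputError("facial features requested but no landmark track given")
        parts.append(window_features(track, windows, facial).set_index("window_start_s"))
    if "F8" in features:
        if trace is None:
            raise InvalidInputError("F8 requested but no RGB trace given")
        f8 = hr_feature_series(trace, windows, rppg_cfg)
        parts.append(f8.set_index("window_start_s")[["F8"]])
    if "F9" in features:
        if sensor_t is None or sensor_bpm is None:
            raise InvalidInputError("F9 requested but no sensor HR series given")
        parts.append(sensor_hr_series(sensor_t, sensor_bpm, windows).set_index("window_start_s"))
    out = pd.concat(parts, axis=1).reset_index()
    return out[["window_start_s", *features]]


def build_training_set(
    window_features_by_game: Mapping[int, pd.DataFrame],
    segments_by_game: Mapping[int, tuple[GameSegment, GameSegment]],
    spec: FeatureSetSpec,
    subject_id: int = 0,
    window_length_s: float = 15.0,
    window_step_s: float = 1.0,
) -> pd.DataFrame:
    """Labeled training samples from the H0/H1 segments of calibration games.

    ``window_features_by_game`` maps game id to a per-window feature table
    (``window_start_s`` + feature columns) covering at least the H0/H1
    windows.  One sample per window; H0 windows are labeled ``boredom`` and
    H1 windows ``stress``.  Windows with a missing (NaN) feature are dropped
    with a logged reason, keeping every emitted vector complete.
    """
    rows = []
    for game_id, (h0, h1) in segments_by_game.items():
        table = window_features_by_game[game_id]
        missing_cols = set(spec.features) - set(table.columns)
        if missing_cols:
            raise InvalidInputError(f"game {game_id}: missing features {sorted(missing_cols)}")
        indexed = table.set_index("window_start_s")
        for seg, label in ((h0, "boredom"), (h1, "stress")):
            for w in enumerate_windows(seg.start_s, seg.end_s, window_length_s, window_step_s):
                try:
                    vec = indexed.loc[w.start_s, list(spec.features)]
                except KeyError:
                    log.info("game %s window %.1f s: features not computed; dropped",
                             game_id, w.start_s)
                    continue
                if not np.all(np.isfinite(np.asarray(vec, dtype=float))):
                    log.info("game %s window %.1f s: incomplete features; dropped",
                             game_id, w.start_s)
                    continue
                rows.append(
                    {**{f: float(vec[f]) for f in spec.features},
                     "label": label, "subject": subject_id,
                     "source": f"game{game_id}", "window_start_s": w.start_s}
                )
    return pd.DataFrame(rows, columns=[*spec.features, *SAMPLE_COLUMNS])


def level_scores(rstress: int, rboredom: int) -> tuple[int, int]:
    """Antisymmetric stress/boredom scores from one Likert report pair."""
    for name, v in (("rstress", rstress), ("rboredom", rboredom)):
        if not (isinstance(v, (int, np.integer)) and 1 <= v <= 5):
            raise InvalidInputError(f"{name} must be an integer in 1..5: {v!r}")
    return int(rstress) - int(rboredom), int(rboredom) - int(rstress)


@dataclass
class LevelSelection:
    """Outcome of self-report-driven evaluation-level selection."""

    stress_levels: list[int]
    boredom_levels: list[int]
    scores: dict[int, tuple[int, int]]  # level -> (stress score, boredom score)
    unevaluable: bool
    reason: str = ""


def select_eval_levels(reports: pd.DataFrame) -> LevelSelection:
    """Pick the evaluation levels of one subject from their self-reports.

    ``reports`` has columns ``level, rstress, rboredom`` (one subject).  The
    two levels with the highest stress score and the two with the highest
    boredom score are selected (ties broken toward the earliest-played
    level); selected levels whose relevant score is < 1 are excluded as
    inconclusive.  A subject with no surviving level in either class is
    unevaluable — reported as a result, not an exception.
    """
    if len(reports) < 1:
        raise InvalidInputError("need at least one self-report")
    scores: dict[int, tuple[int, int]] = {}
    for rec in reports.itertuples(index=False):
        scores[int(rec.level)] = level_scores(int(rec.rstress), int(rec.rboredom))
    levels = sorted(scores)  # play order

    def top_two(score_of) -> list[int]:
        ranked = sorted(levels, key=lambda lv: (-score_of(lv), lv))
        picked = ranked[: min(2, len(ranked))]
        return sorted(lv for lv in picked if score_of(lv) >= 1)

    stress_levels = top_two(lambda lv: scores[lv][0])
    boredom_levels = top_two(lambda lv: scores[lv][1])
    # antisymmetry makes dual membership impossible after the >= 1 filter,
    # but guard anyway: a level eligible for both classes joins neither
    dual = set(stress_levels) & set(boredom_levels)
    stress_levels = [lv for lv in stress_levels if lv not in dual]
    boredom_levels = [lv for lv in boredom_levels if lv not in dual]
    unevaluable = not stress_levels or not boredom_levels
    reason = ""
    if unevaluable:
        reason = "no level with a conclusive self-report in one or both classes"
    return LevelSelection(stress_levels, boredom_levels, scores, unevaluable, reason)


def test_window_starts(
    level_duration_s: float,
    window_length_s: float = 15.0,
    sampling_interval_s: float = 5.0,
) -> list[float]:
    """Starts of test windows [t - L, t) ending at t = L, L+5, ... within a level."""
    starts: list[float] = []
    t = window_length_s
    while t <= level_duration_s + 1e-9:
        starts.append(t - window_length_s)
        t += sampling_interval_s
    return starts


def sample_test_set(
    window_features_by_level: Mapping[int, pd.DataFrame],
    selection: LevelSelection,
    spec: FeatureSetSpec,
    subject_id: int = 0,
) -> pd.DataFrame:
    """Labeled test samples from the selected evaluation levels.

    ``window_features_by_level`` maps level id to the per-window feature
    table already computed on the 5 s test grid.  Samples from stress-class
    levels are labeled ``stress``; boredom-class ones ``boredom``.  A level
    shorter than one window simply contributes no samples.
    """
    rows = []
    for label, level_ids in (("stress", selection.stress_levels),
                             ("boredom", selection.boredom_levels)):
        for lv in level_ids:
            table = window_features_by_level[lv]
            for rec in table.itertuples(index=False):
                vec = {f: float(getattr(rec, f)) for f in spec.features}
                if not all(np.isfinite(v) for v in vec.values()):
                    log.info("level %s window %.1f s: incomplete features; dropped",
                             lv, rec.window_start_s)
                    continue
                rows.append({**vec, "label": label, "subject": subject_id,
                             "source": f"level{lv}",
                             "window_start_s": float(rec.window_start_s)})
    return pd.DataFrame(rows, columns=[*spec.features, *SAMPLE_COLUMNS])
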