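"""Session segmentation: warm-up removal, boredom/stress thirds, moving windows.

A calibration game ramps its difficulty endlessly, so a player passes from
boredom (start) to stress (end).  After discarding the first ``D`` seconds
as warm-up, the remainder of the recording is cut into three equal thirds:
the first third is the boredom segment (H0), the last third the stress
segment (H1), and the middle — whose emotional state is unknown — is
discarded.  Feature extraction then slides a fixed-length window over each
segment of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .exceptions import InvalidInputError, SessionTooShortError

Role = Literal["H0", "H1", "discarded"]

DEFAULT_WARMUP_S = 45.0
DEFAULT_WINDOW_LENGTH_S = 15.0
DEFAULT_WINDOW_STEP_S = 1.0


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window [start_s, start_s + length_s)."""

    start_s: float
    length_s: float = DEFAULT_WINDOW_LENGTH_S

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise InvalidInputError(f"window length must be > 0: {self.length_s}")
        if self.start_s < 0:
            raise InvalidInputError(f"window start must be >= 0: {self.start_s}")

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s


@dataclass(frozen=True)
class GameSegment:
    """A labeled interval of one calibration-game recording."""

    subject_id: int
    game_id: int
    start_s: float
    end_s: float
    role: Role

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise InvalidInputError("segment must have end > start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class EvalSegment:
    """One evaluation-game level played by one subject."""

    subject_id: int
    level_id: int
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise InvalidInputError("segment must have end > start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ManifestEntry:
    """One recording of a subject playing one game or level.

    Times are on the recording's own clock (each game/level is captured as
    its own stream), so ``start_s`` is normally 0.
    """

    kind: Literal["calibration", "evaluation"]
    id: int
    start_s: float
    end_s: float
    excluded: bool = False
    reason: str = ""


@dataclass
class SessionManifest:
    """All recordings of one subject, with exclusion bookkeeping."""

    subject_id: int
    entries: list[ManifestEntry] = field(default_factory=list)

    def validate(self) -> None:
        for e in self.entries:
            if not e.end_s > e.start_s >= 0:
                raise InvalidInputError(
                    f"subject {self.subject_id}: bad interval [{e.start_s}, {e.end_s})"
                )
        keys = [(e.kind, e.id) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise InvalidInputError(f"subject {self.subject_id}: duplicate recording ids")

    def calibration_entries(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.kind == "calibration"]

    def evaluation_entries(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.kind == "evaluation"]

    @property
    def excluded(self) -> bool:
        """Whole-subject exclusion: any excluded calibration recording taints all."""
        return any(e.excluded for e in self.calibration_entries())


def segment_calibration(
    duration_s: float,
    warmup_s: float = DEFAULT_WARMUP_S,
    *,
    subject_id: int = 0,
    game_id: int = 0,
) -> tuple[GameSegment, GameSegment, list[GameSegment]]:
    """Cut one calibration recording [0, duration_s) into H0 / H1 / discarded.

    The first ``warmup_s`` seconds are dropped.  The remainder ``R`` is split
    into thirds of ``L = floor(R / 3)`` whole seconds: H0 = [D, D+L) and
    H1 = [duration - L, duration); any slack from flooring stays in the
    discarded middle, keeping H0 and H1 equal length and label-pure.

    Returns ``(h0, h1, discarded)``.

    Raises
    ------
    SessionTooShortError
        If ``duration_s <= warmup_s + 3`` (each third must be >= 1 s).
    """
    if warmup_s < 0:
        raise InvalidInputError(f"warm-up must be >= 0: {warmup_s}")
    if duration_s <= warmup_s + 3:
        raise SessionTooShortError(
            f"recording of {duration_s} s leaves no room for thirds after "
            f"{warmup_s} s warm-up"
        )
    remainder = duration_s - warmup_s
    third = float(math.floor(remainder / 3))
    h0 = GameSegment(subject_id, game_id, warmup_s, warmup_s + third, "H0")
    h1 = GameSegment(subject_id, game_id, duration_s - third, duration_s, "H1")
    discarded = [GameSegment(subject_id, game_id, 0.0, warmup_s, "discarded")]
    if h1.start_s > h0.end_s:
        discarded.append(GameSegment(subject_id, game_id, h0.end_s, h1.start_s, "discarded"))
    return h0, h1, discarded


def enumerate_windows(
    start_s: float,
    end_s: float,
    length_s: float = DEFAULT_WINDOW_LENGTH_S,
    step_s: float = DEFAULT_WINDOW_STEP_S,
) -> list[AnalysisWindow]:
    """All windows [start + k*step, start + k*step + length) inside [start, end).

    An interval shorter than one window yields an empty list (not an error).
    """
    if length_s <= 0 or step_s <= 0:
        raise InvalidInputError("window length and step must be > 0")
    span = end_s - start_s
    if span < length_s:
        return []
    count = int(math.floor((span - length_s) / step_s + 1e-9)) + 1
    return [AnalysisWindow(start_s + k * step_s, length_s) for k in range(count)]


def window_overlap_fraction(length_s: float, step_s: float) -> float:
    """Fraction of span shared by consecutive windows: (length - step) / length."""
    if length_s <= 0 or step_s <= 0:
        raise InvalidInputError("window length and step must be > 0")
    return max(0.0, (length_s - step_s) / length_s)


def count_segments(manifests: Iterable[SessionManifest]) -> dict:
    """Bookkeeping over a cohort's manifests.

    Counts (H0, H1) calibration pairs and evaluation segments after applying
    whole-subject exclusion: one problematic calibration recording discards
    every H0/H1 pair of that subject.
    """
    manifests = list(manifests)
    for m in manifests:
        m.validate()
    excluded_subjects = sorted(m.subject_id for m in manifests if m.excluded)
    pairs = 0
    eval_segments = 0
    for m in manifests:
        if not m.excluded:
            pairs += len(m.calibration_entries())
        eval_segments += sum(not e.excluded for e in m.evaluation_entries())
    return {
        "subjects": len(manifests),
        "excluded_subjects": excluded_subjects,
        "h0_h1_pairs": pairs,
        "h0_segments": pairs,
        "h1_segments": pairs,
        "eval_segments": eval_segments,
    }
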