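"""Synthetic gaming sessions: landmark tracks, RGB pulse traces, sensor HR,
manifests and self-reports.

The generator emulates the *elicitation design* of the method's calibration
and evaluation games: a calibration session drives the player from boredom
to stress, and the seven evaluation levels follow a fixed pattern with two
designed-stressful levels (3 and 6), two designed-boring ones (4 and 7) and
three of unconstrained affect.  Physiology and behaviour are simulated per
state:

* heart rate follows an Ornstein-Uhlenbeck process around the state mean;
* the pulse waveform sin(2*pi*Int f dt) + 0.3 x second harmonic is injected
  into the RGB channels with green-dominant amplitudes (R:G:B =
  0.3 : 1.0 : 0.6), atop a baseline, white noise and occasional step
  artifacts;
* landmarks are a fixed neutral 68-point template plus a mean-reverting
  rigid random walk (head motion), Poisson blink events that collapse the
  eye contours over 300 ms, and Poisson mouth/brow events;
* the wrist sensor samples the true HR at 1 Hz with +-1 bpm jitter;
* self-reports follow the scheduled states (stressful levels draw
  rstress from {4,5} and rboredom from {1,2}; conversely for boring ones),
  with a configurable confusion probability.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .facial import LandmarkTrack, RIGHT_EYE, LEFT_EYE
from .rppg import RGBTrace
from .segmentation import ManifestEntry, SessionManifest

State = Literal["boredom", "stress"]

#: design pattern of the seven evaluation levels (1-based level id -> intent)
EVAL_LEVEL_DESIGN: dict[int, str] = {
    1: "any", 2: "any", 3: "stress", 4: "boredom", 5: "any", 6: "stress", 7: "boredom",
}

DEFAULT_CALIBRATION_DURATION_S = 165.0
DEFAULT_LEVEL_DURATION_S = 90.0


def neutral_face_template() -> np.ndarray:
    """A fixed, synthetic neutral 68-point face in iBUG-68 order.

    Coordinates are arbitrary but fixed: a ~160 x 190 px face centered at
    (320, 240) in image convention (y grows downward).
    """
    pts = np.zeros((68, 2))
    # jaw 0-16: half-ellipse from left cheek through chin to right cheek
    th = np.linspace(0.0, np.pi, 17)
    pts[0:17, 0] = -80.0 * np.cos(th)
    pts[0:17, 1] = 90.0 * np.sin(th)
    # brows 17-21 (subject right / image left) and 22-26, gentle arcs
    arc = 6.0 * np.sin(np.linspace(0, np.pi, 5))
    pts[17:22, 0] = np.linspace(-60, -20, 5)
    pts[17:22, 1] = -40.0 - arc
    pts[22:27, 0] = np.linspace(20, 60, 5)
    pts[22:27, 1] = -40.0 - arc
    # nose bridge 27-30 and lower nose 31-35
    pts[27:31, 0] = 0.0
    pts[27:31, 1] = np.linspace(-30, 10, 4)
    pts[31:36] = [(-12, 18), (-6, 20), (0, 22), (6, 20), (12, 18)]
    # eyes 36-41 / 42-47: six-point open-eye hexagons
    pts[36:42] = [(-52, -20), (-46, -26), (-34, -26), (-28, -20), (-34, -14), (-46, -14)]
    pts[42:48] = [(28, -20), (34, -26), (46, -26), (52, -20), (46, -14), (34, -14)]
    # outer lip 48-59 and inner lip 60-67
    pts[48:60] = [
        (-25, 55), (-15, 48), (-7, 46), (0, 45), (7, 46), (15, 48),
        (25, 55), (15, 62), (7, 64), (0, 65), (-7, 64), (-15, 62),
    ]
    pts[60:68] = [(-18, 55), (-8, 52), (0, 51), (8, 52), (18, 55), (8, 58), (0, 59), (-8, 58)]
    return pts + np.array([320.0, 240.0])


@dataclass(frozen=True)
class StateParams:
    """Per-state physiological and behavioural rates."""

    hr_mean_bpm: float
    hr_sigma_bpm: float = 3.0       # stationary SD of the OU heart-rate process
    blink_rate_hz: float = 0.25     # blinks per second
    head_step_px: float = 0.5       # per-frame scale of the rigid head walk
    event_rate_hz: float = 0.05     # mouth/brow events per second

    def __post_init__(self) -> None:
        if not 45.0 <= self.hr_mean_bpm <= 240.0:
            raise InvalidInputError(f"HR mean outside [45, 240]: {self.hr_mean_bpm}")
        for name in ("hr_sigma_bpm", "blink_rate_hz", "head_step_px", "event_rate_hz"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimProfile:
    """All knobs of one simulated subject."""

    boredom: StateParams
    stress: StateParams
    pulse_amp_rgb: tuple[float, float, float] = (0.3, 1.0, 0.6)
    pulse_amp: float = 1.0          # master pulse amplitude, 8-bit pixel units
    noise_scale: float = 0.3        # white-noise SD per channel, pixel units
    artifact_rate_hz: float = 1 / 60  # step-artifact events per second
    artifact_step_px: float = 3.0
    rgb_baseline: tuple[float, float, float] = (120.0, 110.0, 100.0)
    report_confusion: float = 0.0   # probability a self-report contradicts the design

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.pulse_amp_rgb) or self.pulse_amp < 0:
            raise InvalidInputError("pulse amplitudes must be >= 0")
        if self.noise_scale < 0 or self.artifact_rate_hz < 0:
            raise InvalidInputError("noise and artifact rates must be >= 0")

    def params(self, state: State) -> StateParams:
        return self.boredom if state == "boredom" else self.stress


def default_profile(effect: float = 1.0, hr_base_bpm: float = 65.0) -> SimProfile:
    """The study conditions: a boredom/stress pair separated by ``effect``.

    At ``effect=1`` the stress state has +20 bpm mean HR and doubled blink /
    head-motion / facial-event rates; at ``effect=0`` the states are
    identical (a null subject).
    """
    if effect < 0:
        raise InvalidInputError("effect size must be >= 0")
    bored = StateParams(hr_mean_bpm=hr_base_bpm, blink_rate_hz=0.25,
                        head_step_px=0.5, event_rate_hz=0.05)
    stressed = StateParams(
        hr_mean_bpm=min(hr_base_bpm + 20.0 * effect, 240.0),
        blink_rate_hz=bored.blink_rate_hz * (1.0 + effect),
        head_step_px=bored.head_step_px * (1.0 + effect),
        event_rate_hz=bored.event_rate_hz * (1.0 + effect),
    )
    return SimProfile(boredom=bored, stress=stressed)


@dataclass
class SimSession:
    """One simulated recording with its ground truth."""

    fps: float
    duration_s: float
    schedule: list[tuple[State, float, float]]
    track: LandmarkTrack
    trace: RGBTrace
    sensor_t: np.ndarray
    sensor_bpm: np.ndarray
    hr_truth: np.ndarray  # per-frame true HR (bpm)

    def state_at(self, t: float) -> State:
        for state, a, b in self.schedule:
            if a <= t < b:
                return state
        return self.schedule[-1][0]


def _validate_schedule(schedule: Sequence[tuple[State, float, float]]) -> list[tuple[State, float, float]]:
    sched = [(s, float(a), float(b)) for s, a, b in schedule]
    if not sched:
        raise InvalidInputError("schedule must not be empty")
    prev_end = 0.0
    for state, a, b in sched:
        if state not in ("boredom", "stress"):
            raise InvalidInputError(f"unknown state {state!r}")
        if b <= a or a < prev_end - 1e-9:
            raise InvalidInputError("schedule intervals must be ordered and non-overlapping")
        prev_end = b
    return sched


def _event_times(rng: np.random.Generator, rate_per_frame: np.ndarray) -> np.ndarray:
    """Frame indices of Poisson events with per-frame intensity."""
    return np.flatnonzero(rng.random(len(rate_per_frame)) < rate_per_frame)


def simulate_session(
    profile: SimProfile,
    schedule: Sequence[tuple[State, float, float]],
    fps: float = 50.0,
    seed: int = 0,
) -> SimSession:
    """Synthesize one recording following a boredom/stress state schedule.

    ``schedule`` is an ordered list of ``(state, start_s, end_s)`` covering
    [0, T).  Returns all streams on a common session clock, plus the true
    HR trajectory for oracle checks.
    """
    sched = _validate_schedule(schedule)
    rng = np.random.default_rng(seed)
    duration = sched[-1][2]
    n = int(round(duration * fps))
    dt = 1.0 / fps
    t = np.arange(n) * dt

    # per-frame state-dependent parameters
    state_idx = np.zeros(n, dtype=int)  # 0 = boredom, 1 = stress
    for state, a, b in sched:
        if state == "stress":
            state_idx[(t >= a) & (t < b)] = 1
    pb, ps = profile.boredom, profile.stress
    mu = np.where(state_idx == 0, pb.hr_mean_bpm, ps.hr_mean_bpm)
    sigma = np.where(state_idx == 0, pb.hr_sigma_bpm, ps.hr_sigma_bpm)
    blink_rate = np.where(state_idx == 0, pb.blink_rate_hz, ps.blink_rate_hz)
    head_step = np.where(state_idx == 0, pb.head_step_px, ps.head_step_px)
    event_rate = np.where(state_idx == 0, pb.event_rate_hz, ps.event_rate_hz)

    # heart rate: OU around the state mean, stationary SD = sigma
    theta = 0.2  # mean-reversion rate, 1/s
    hr = np.empty(n)
    hr[0] = mu[0]
    noise = rng.standard_normal(n)
    sw = sigma * np.sqrt(2.0 * theta)
    for k in range(1, n):
        hr[k] = hr[k - 1] + theta * (mu[k] - hr[k - 1]) * dt + sw[k] * np.sqrt(dt) * noise[k]
    np.clip(hr, 45.0, 240.0, out=hr)

    # pulse waveform injected into RGB with green-dominant amplitudes
    phase = 2.0 * np.pi * np.cumsum(hr / 60.0) * dt
    pulse = np.sin(phase) + 0.3 * np.sin(2.0 * phase)
    amps = profile.pulse_amp * np.asarray(profile.pulse_amp_rgb)
    rgb = np.asarray(profile.rgb_baseline) + pulse[:, None] * amps[None, :]
    rgb += profile.noise_scale * rng.standard_normal((n, 3))
    for k in _event_times(rng, np.full(n, profile.artifact_rate_hz * dt)):
        rgb[k:] += profile.artifact_step_px * rng.standard_normal(3)
    np.clip(rgb, 0.0, 255.0, out=rgb)

    # landmarks: template + mean-reverting rigid walk + blinks + facial events
    template = neutral_face_template()
    kappa = 0.02  # per-frame pull toward the resting head pose
    steps = head_step[:, None] * rng.standard_normal((n, 2))
    offset = np.empty((n, 2))
    offset[0] = 0.0
    for k in range(1, n):
        offset[k] = offset[k - 1] * (1.0 - kappa) + steps[k]
    points = template[None, :, :] + offset[:, None, :]

    closure = np.zeros(n)  # eye closure in [0, 1]
    blink_len = max(int(round(0.3 * fps)), 2)
    ramp = 1.0 - np.abs(np.linspace(-1.0, 1.0, blink_len))
    for k in _event_times(rng, blink_rate * dt):
        hi = min(k + blink_len, n)
        closure[k:hi] = np.maximum(closure[k:hi], ramp[: hi - k])
    for eye in (RIGHT_EYE, LEFT_EYE):
        center_y = points[:, eye, 1].mean(axis=1, keepdims=True)
        points[:, eye, 1] = center_y + (points[:, eye, 1] - center_y) * (1.0 - closure)[:, None]

    event_len = max(int(round(0.5 * fps)), 2)
    eramp = 1.0 - np.abs(np.linspace(-1.0, 1.0, event_len))
    for k in _event_times(rng, event_rate * dt):
        hi = min(k + event_len, n)
        c = eramp[: hi - k]
        if rng.random() < 0.5:  # mouth event: scale lips about the mouth centroid
            lips = slice(48, 68)
            mouth_c = points[k:hi, lips].mean(axis=1, keepdims=True)
            points[k:hi, lips] = mouth_c + (points[k:hi, lips] - mouth_c) * (
                1.0 + 0.3 * c[:, None, None]
            )
        else:  # brow event: furrow — brows drop and inner points move inward
            brows = slice(17, 27)
            points[k:hi, brows, 1] += 5.0 * c[:, None]
            points[k:hi, 21, 0] += 4.0 * c
            points[k:hi, 22, 0] -= 4.0 * c

    sensor_t = np.arange(0.0, duration, 1.0)
    frame_of = np.minimum((sensor_t * fps).astype(int), n - 1)
    sensor_bpm = hr[frame_of] + rng.uniform(-1.0, 1.0, len(sensor_t))

    return SimSession(
        fps=fps,
        duration_s=duration,
        schedule=sched,
        track=LandmarkTrack(fps=fps, points=points),
        trace=RGBTrace(fps=fps, rgb=rgb),
        sensor_t=sensor_t,
        sensor_bpm=sensor_bpm,
        hr_truth=hr,
    )


def calibration_schedule(duration_s: float = DEFAULT_CALIBRATION_DURATION_S) -> list[tuple[State, float, float]]:
    """Boredom for the first half, stress for the second — the elicitation
    ramp of a calibration game reduced to its two labeled extremes."""
    half = duration_s / 2.0
    return [("boredom", 0.0, half), ("stress", half, duration_s)]


def level_schedule(level_id: int, duration_s: float = DEFAULT_LEVEL_DURATION_S) -> list[tuple[State, float, float]]:
    """State schedule of one evaluation level per the seven-level design."""
    design = EVAL_LEVEL_DESIGN[level_id]
    if design == "stress":
        return [("stress", 0.0, duration_s)]
    if design == "boredom":
        return [("boredom", 0.0, duration_s)]
    half = duration_s / 2.0
    return [("boredom", 0.0, half), ("stress", half, duration_s)]


def _report_for_level(design: str, rng: np.random.Generator, confusion: float) -> tuple[int, int]:
    """Draw (rstress, rboredom) Likert values consistent with a level's design."""
    kind = design
    if design in ("stress", "boredom") and rng.random() < confusion:
        kind = "boredom" if design == "stress" else "stress"
    if kind == "stress":
        return int(rng.integers(4, 6)), int(rng.integers(1, 3))
    if kind == "boredom":
        return int(rng.integers(1, 3)), int(rng.integers(4, 6))
    v = int(rng.integers(2, 4))
    return v, v  # inconclusive: equal scores, filtered out downstream


@dataclass
class SimSubject:
    subject_id: int
    profile: SimProfile
    manifest: SessionManifest
    calibration: dict[int, SimSession] = field(default_factory=dict)  # game id -> session
    evaluation: dict[int, SimSession] = field(default_factory=dict)   # level id -> session


@dataclass
class SimCohort:
    study: int
    subjects: list[SimSubject]
    reports: pd.DataFrame  # columns: subject, level, rstress, rboredom

    @property
    def manifests(self) -> list[SessionManifest]:
        return [s.manifest for s in self.subjects]


def cohort_manifests(
    n_subjects: int,
    study: int,
    calibration_duration_s: float = DEFAULT_CALIBRATION_DURATION_S,
    level_duration_s: float = DEFAULT_LEVEL_DURATION_S,
    excluded_subjects: Sequence[int] = (),
) -> list[SessionManifest]:
    """Session manifests of a study cohort, without any signal synthesis.

    Study 1: 3 calibration games per subject.  Study 2: 3 calibration games
    plus 7 evaluation levels.  Subjects in ``excluded_subjects`` have their
    calibration recordings flagged, which (per whole-subject exclusion)
    discards all their H0/H1 pairs.
    """
    if n_subjects < 1:
        raise InvalidInputError("need at least one subject")
    if study not in (1, 2):
        raise InvalidInputError(f"study must be 1 or 2: {study}")
    manifests = []
    for sid in range(1, n_subjects + 1):
        excl = sid in excluded_subjects
        entries = [
            ManifestEntry("calibration", g, 0.0, calibration_duration_s,
                          excluded=excl, reason="calibration problem" if excl else "")
            for g in (1, 2, 3)
        ]
        if study == 2:
            entries += [
                ManifestEntry("evaluation", m, 0.0, level_duration_s)
                for m in range(1, 8)
            ]
        manifests.append(SessionManifest(subject_id=sid, entries=entries))
    return manifests


def simulate_cohort(
    n_subjects: int,
    study: int = 2,
    seed: int = 0,
    effect: float = 1.0,
    fps: float = 50.0,
    calibration_duration_s: float = DEFAULT_CALIBRATION_DURATION_S,
    level_duration_s: float = DEFAULT_LEVEL_DURATION_S,
    excluded_subjects: Sequence[int] = (),
    profiles: Sequence[SimProfile] | None = None,
) -> SimCohort:
    """Simulate a full study cohort.

    Each subject gets three calibration sessions (boredom -> stress) and,
    for study 2, seven evaluation levels following the fixed design, plus
    self-reports consistent with the scheduled states.  Subject
    heterogeneity: baseline HR jittered +-5 bpm and behavioural rates
    scaled by U(0.8, 1.2) unless explicit ``profiles`` are given.
    """
    manifests = cohort_manifests(
        n_subjects, study, calibration_duration_s, level_duration_s, excluded_subjects
    )
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n_subjects)
    subjects = []
    report_rows = []
    for manifest, sseq in zip(manifests, subject_seeds):
        sid = manifest.subject_id
        rng = np.random.default_rng(sseq)
        if profiles is not None:
            profile = profiles[sid - 1]
        else:
            base = default_profile(effect, hr_base_bpm=65.0 + rng.uniform(-5.0, 5.0))
            scale = rng.uniform(0.8, 1.2)
            profile = dataclasses.replace(
                base,
                boredom=dataclasses.replace(
                    base.boredom,
                    blink_rate_hz=base.boredom.blink_rate_hz * scale,
                    head_step_px=base.boredom.head_step_px * scale,
                ),
                stress=dataclasses.replace(
                    base.stress,
                    blink_rate_hz=base.stress.blink_rate_hz * scale,
                    head_step_px=base.stress.head_step_px * scale,
                ),
            )
        subject = SimSubject(subject_id=sid, profile=profile, manifest=manifest)
        for g in (1, 2, 3):
            subject.calibration[g] = simulate_session(
                profile, calibration_schedule(calibration_duration_s), fps=fps,
                seed=int(rng.integers(2**31)),
            )
        if study == 2:
            for m in range(1, 8):
                subject.evaluation[m] = simulate_session(
                    profile, level_schedule(m, level_duration_s), fps=fps,
                    seed=int(rng.integers(2**31)),
                )
                rs, rb = _report_for_level(EVAL_LEVEL_DESIGN[m], rng, profile.report_confusion)
                report_rows.append({"subject": sid, "level": m, "rstress": rs, "rboredom": rb})
        subjects.append(subject)
    reports = pd.DataFrame(report_rows, columns=["subject", "level", "rstress", "rboredom"])
    return SimCohort(study=study, subjects=subjects, reports=reports)
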