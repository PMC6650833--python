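"""Remote photoplethysmography: per-window heart-rate estimation (feature F8).

The cardiac pulse modulates the light absorbed by facial skin, leaving a
small periodic component in the mean R/G/B values of a facial region.
Following the blind-source-separation family of rPPG methods, each analysis
window is processed as:

1. per-channel linear detrend and z-normalization;
2. independent component analysis (FastICA, 3 components, seeded);
3. Hamming-windowed, zero-padded power spectrum of each component
   (frequency-bin spacing <= 1 bpm);
4. the component with the largest in-band (0.75-4 Hz) peak-to-total power
   ratio is taken as the pulse; HR = 60 x peak frequency;
5. a history constraint rejects jumps larger than 12 bpm between
   consecutive windows, falling back to the next-highest in-band peak and,
   failing that, carrying the previous estimate forward unaccepted.

Feature F9 (sensor heart rate) is simply the per-window mean of 1 Hz
chest/wrist-sensor samples and involves none of this machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .exceptions import DegenerateSignalError, InvalidInputError
from .segmentation import AnalysisWindow

BPM_MIN, BPM_MAX = 45.0, 240.0


@dataclass
class RppgConfig:
    """Tunables of the pulse-recovery chain.

    band_hz: physiological search band (default 0.75-4 Hz = 45-240 bpm).
    history_max_jump_bpm: maximal accepted change between consecutive
        accepted estimates (default 12 bpm).
    min_peak_ratio: minimal in-band peak-to-total power ratio for a window
        to yield an estimate at all; below it the window is reported as
        having no estimate.
    max_bin_bpm: upper bound on spectral bin spacing, enforced by zero
        padding (default 1 bpm).
    seed: RNG seed for FastICA initialization.
    """

    band_hz: tuple[float, float] = (0.75, 4.0)
    history_max_jump_bpm: float = 12.0
    min_peak_ratio: float = 0.05
    max_bin_bpm: float = 1.0
    seed: int = 0


@dataclass
class RGBTrace:
    """Per-frame spatial mean of R, G, B over the facial region."""

    fps: float
    rgb: np.ndarray  # (n_frames, 3)
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidInputError(f"fps must be > 0: {self.fps}")
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 2 or self.rgb.shape[1] != 3 or len(self.rgb) < 1:
            raise InvalidInputError(f"expected (n, 3) RGB array, got {self.rgb.shape}")
        if not np.all(np.isfinite(self.rgb)):
            raise InvalidInputError("RGB values must be finite")

    def __len__(self) -> int:
        return len(self.rgb)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.rgb)) / self.fps

    def window_slice(self, window: AnalysisWindow) -> np.ndarray:
        t = self.t
        lo = int(np.searchsorted(t, window.start_s - 1e-9, side="left"))
        hi = int(np.searchsorted(t, window.end_s - 1e-9, side="left"))
        if lo >= hi or window.end_s > self.t0 + len(self) / self.fps + 1e-9:
            raise InvalidInputError(f"window {window} not covered by trace")
        return self.rgb[lo:hi]


@dataclass
class HREstimate:
    """One window's heart-rate estimate.

    ``bpm`` is None when the window yielded no estimate at all;
    ``accepted`` is False when the history constraint rejected the window
    (``bpm`` then carries the previous estimate forward).
    """

    window_start_s: float
    bpm: float | None
    peak_power_ratio: float
    accepted: bool


def extract_rgb_trace(
    frames: Iterable[np.ndarray],
    rois: Sequence[tuple[int, int, int, int]] | tuple[int, int, int, int],
    fps: float,
) -> RGBTrace:
    """Average each video frame's pixels over a rectangular region of interest.

    ``rois`` is one ``(x, y, w, h)`` rectangle or one per frame.  Frames are
    ``(H, W, 3)`` arrays.  This is convenience plumbing for real video input;
    synthetic traces bypass it entirely.
    """
    frames = list(frames)
    if isinstance(rois, tuple) and len(rois) == 4 and np.isscalar(rois[0]):
        rois = [rois] * len(frames)  # type: ignore[list-item]
    means = []
    for frame, (x, y, w, h) in zip(frames, rois, strict=True):
        if w <= 0 or h <= 0:
            raise InvalidInputError(f"empty ROI {(x, y, w, h)}")
        frame = np.asarray(frame)
        if frame.ndim != 3 or frame.shape[2] != 3:
            raise InvalidInputError(f"expected (H, W, 3) frame, got {frame.shape}")
        if y + h > frame.shape[0] or x + w > frame.shape[1] or x < 0 or y < 0:
            raise InvalidInputError("ROI outside frame bounds")
        means.append(frame[y : y + h, x : x + w].reshape(-1, 3).mean(axis=0))
    return RGBTrace(fps=fps, rgb=np.asarray(means, dtype=float))


def condition_trace(trace: RGBTrace, window: AnalysisWindow) -> np.ndarray:
    """Linearly detrend then z-normalize each channel over the window.

    Returns a (n_frames, 3) array with zero mean and unit variance per
    channel.  Raises DegenerateSignalError if a channel has (numerically)
    no variance left after detrending.
    """
    chunk = trace.window_slice(window)
    detrended = sps.detrend(chunk, axis=0, type="linear")
    std = detrended.std(axis=0)
    scale_ref = np.abs(chunk).max() + 1.0
    if np.any(std <= 1e-12 * scale_ref):
        raise DegenerateSignalError("channel has no variance after detrending")
    return (detrended - detrended.mean(axis=0)) / std


def _power_spectrum(x: np.ndarray, fps: float, max_bin_bpm: float) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-windowed, zero-padded power spectra of columns of ``x``."""
    n = x.shape[0]
    min_nfft = int(np.ceil(fps * 60.0 / max_bin_bpm))  # bin spacing <= max_bin_bpm
    nfft = 1 << max(int(np.ceil(np.log2(max(min_nfft, n)))), 1)
    win = np.hamming(n)[:, None]
    spec = np.abs(np.fft.rfft(x * win, n=nfft, axis=0)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fps)
    return freqs, spec


def _inband_peaks(power: np.ndarray, freqs: np.ndarray, band: tuple[float, float]) -> list[tuple[float, float]]:
    """(frequency, power) of in-band spectral peaks, highest first."""
    mask = (freqs >= band[0]) & (freqs <= band[1])
    p, f = power[mask], freqs[mask]
    if len(p) == 0:
        return []
    idx, _ = sps.find_peaks(p)
    peaks = set(idx.tolist())
    peaks.add(int(np.argmax(p)))  # global max counts even at a band edge
    ordered = sorted(peaks, key=lambda i: -p[i])
    return [(float(f[i]), float(p[i])) for i in ordered]


def estimate_hr_window(
    trace: RGBTrace,
    window: AnalysisWindow,
    cfg: RppgConfig | None = None,
    prev_bpm: float | None = None,
) -> HREstimate:
    """Estimate mean heart rate over one analysis window.

    A degenerate signal or an in-band peak ratio below ``cfg.min_peak_ratio``
    yields a no-estimate result (``bpm=None`` if there is no history to carry,
    otherwise the previous bpm, unaccepted) rather than an exception.
    """
    cfg = cfg or RppgConfig()
    try:
        x = condition_trace(trace, window)
    except DegenerateSignalError:
        return HREstimate(window.start_s, prev_bpm, 0.0, False)
    ica = FastICA(n_components=3, random_state=cfg.seed, whiten="unit-variance", max_iter=1000)
    with warnings.catch_warnings():
        # a non-converged unmixing is still a usable rotation; spectra decide
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(x)
    freqs, spec = _power_spectrum(sources, trace.fps, cfg.max_bin_bpm)
    mask = (freqs >= cfg.band_hz[0]) & (freqs <= cfg.band_hz[1])
    best_ratio, best_comp = -1.0, 0
    for c in range(spec.shape[1]):
        inband = spec[mask, c]
        total = inband.sum()
        ratio = float(inband.max() / total) if total > 0 else 0.0
        if ratio > best_ratio:
            best_ratio, best_comp = ratio, c
    if best_ratio < cfg.min_peak_ratio:
        return HREstimate(window.start_s, prev_bpm, best_ratio, False)
    peaks = _inband_peaks(spec[:, best_comp], freqs, cfg.band_hz)
    inband_total = float(spec[mask, best_comp].sum())
    bpm = 60.0 * peaks[0][0]
    if prev_bpm is not None and abs(bpm - prev_bpm) > cfg.history_max_jump_bpm:
        for f, p in peaks[1:]:
            # a fallback peak must be substantial itself, not a noise sidelobe
            if p / inband_total < cfg.min_peak_ratio:
                break
            if abs(60.0 * f - prev_bpm) <= cfg.history_max_jump_bpm:
                return HREstimate(window.start_s, 60.0 * f, best_ratio, True)
        return HREstimate(window.start_s, prev_bpm, best_ratio, False)
    return HREstimate(window.start_s, bpm, best_ratio, True)


def hr_feature_series(
    trace: RGBTrace,
    windows: Sequence[AnalysisWindow],
    cfg: RppgConfig | None = None,
) -> pd.DataFrame:
    """Feature F8 for an ordered sequence of windows.

    The history constraint is threaded through consecutive windows.  Windows
    with no estimate carry the last accepted bpm forward; a leading run with
    no estimate at all is reported as NaN (dataset assembly drops those
    windows together with their facial features).

    Returns columns ``window_start_s, F8, accepted``.
    """
    cfg = cfg or RppgConfig()
    rows = []
    prev: float | None = None
    for w in windows:
        est = estimate_hr_window(trace, w, cfg, prev_bpm=prev)
        if est.accepted:
            prev = est.bpm
        rows.append(
            {
                "window_start_s": w.start_s,
                "F8": est.bpm if est.bpm is not None else np.nan,
                "accepted": est.accepted,
            }
        )
    return pd.DataFrame(rows, columns=["window_start_s", "F8", "accepted"])


def sensor_hr_series(
    t: np.ndarray,
    bpm: np.ndarray,
    windows: Sequence[AnalysisWindow],
) -> pd.DataFrame:
    """Feature F9: mean of 1 Hz sensor samples whose timestamps fall in each window."""
    t = np.asarray(t, dtype=float)
    bpm = np.asarray(bpm, dtype=float)
    if t.shape != bpm.shape:
        raise InvalidInputError("sensor t and bpm must have equal length")
    rows = []
    for w in windows:
        mask = (t >= w.start_s) & (t < w.end_s)
        rows.append(
            {
                "window_start_s": w.start_s,
                "F9": float(bpm[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["window_start_s", "F9"])
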