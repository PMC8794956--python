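"""High-EMG / movement classification from one EMG channel.

Movement shows up in the electromyogram as bursts of broadband power.  The
classifier is threshold-based: the 15 Hz high-passed EMG is reduced to a
1-s RMS series, and a second is called "high tone" when its log RMS exceeds
the point where the slope of the smoothed cumulative distribution drops
below 1 when scanning upward from the main (quiet) mode.  Because quiet-
second RMS values cluster tightly in log units, the smoothed density at the
quiet mode is well above 1 and the rule places the threshold in the valley
between the quiet and movement modes of a bimodal recording.  Log RMS is
centered before thresholding, which makes the rule invariant to rescaling
the raw signal by any positive constant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

logger = logging.getLogger(__name__)

__all__ = [
    "RmsSeries",
    "EmgToneMask",
    "highpass_emg",
    "emg_rms_series",
    "high_tone_threshold",
    "emg_high_tone",
]


@dataclass
class RmsSeries:
    """Non-overlapping 1-s RMS values (uV) and their start times (s)."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("RMS values must be non-negative")
        if len(self.values) != len(self.times):
            raise ValueError("values and times must align")


@dataclass
class EmgToneMask:
    """Per-second high-tone calls plus the threshold that produced them."""

    mask: np.ndarray            # bool per second
    threshold_log_uv: float     # natural-log uV; +inf when degenerate
    times: np.ndarray
    slope_grid: np.ndarray = None
    slope_values: np.ndarray = None

    @property
    def high_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


def highpass_emg(x: np.ndarray, fs: float = 250.0,
                 cutoff_hz: float = 15.0, order: int = 6) -> np.ndarray:
    """15 Hz 6th-order zero-phase Butterworth high-pass (removes motion
    baseline and most cardiac artifact while keeping muscle-band power)."""
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= 3 * padlen:
        raise ValueError("series too short for zero-phase high-pass filtering")
    return signal.sosfiltfilt(sos, x, axis=-1)


def emg_rms_series(x: np.ndarray, fs: float = 250.0, t0_s: float = 0.0) -> RmsSeries:
    """Root-mean-square over non-overlapping 1-s periods; a trailing partial
    second is dropped."""
    x = np.asarray(x, dtype=float)
    n_per = int(round(fs))
    n_sec = x.size // n_per
    if n_sec < 1:
        raise ValueError("need at least one full second of signal")
    vals = np.sqrt((x[: n_sec * n_per] ** 2).reshape(n_sec, n_per).mean(axis=1))
    return RmsSeries(values=vals, times=t0_s + np.arange(n_sec, dtype=float))


def high_tone_threshold(rms: RmsSeries, grid_size: int = 512,
                        min_periods: int = 300) -> EmgToneMask:
    """Threshold the log RMS series at the CDF-slope-below-1 point.

    The empirical CDF of centered natural-log RMS is kernel-smoothed
    (Gaussian kernel, Silverman bandwidth) on a uniform grid; its slope is
    the kernel density estimate.  Scanning upward from the main mode, the
    threshold is the first grid point where the slope drops below 1; periods
    with log RMS strictly above it are "high tone".  A degenerate (constant)
    series, or one whose density never reaches 1, yields an all-false mask
    with a warning.
    """
    vals = np.asarray(rms.values, dtype=float)
    if vals.size < min_periods:
        warnings.warn(
            f"only {vals.size} RMS periods (< {min_periods}); "
            "threshold estimate may be unstable"
        )
    positive = vals[vals > 0]
    if positive.size == 0 or np.ptp(np.log(np.maximum(vals, np.min(positive, initial=1.0) * 1e-6))) < 1e-9:
        warnings.warn("degenerate (constant) RMS series; no high-tone periods")
        return EmgToneMask(np.zeros(vals.size, dtype=bool), np.inf, rms.times)
    floor = positive.min() * 1e-3
    logr = np.log(np.maximum(vals, floor))
    center = logr.mean()
    z = logr - center

    std = z.std(ddof=1)
    iqr = np.subtract(*np.percentile(z, [75, 25]))
    scale = min(std, iqr / 1.349) if iqr > 0 else std
    h = 0.9 * scale * z.size ** (-0.2)
    if h <= 0:
        warnings.warn("degenerate RMS spread; no high-tone periods")
        return EmgToneMask(np.zeros(vals.size, dtype=bool), np.inf, rms.times)
    grid = np.linspace(z.min() - 3 * h, z.max() + 3 * h, grid_size)
    kde = stats.gaussian_kde(z, bw_method=h / z.std(ddof=1))
    slope = kde(grid)  # slope of the smoothed CDF = smoothed density

    mode_idx = int(np.argmax(slope))
    below = np.flatnonzero(slope[mode_idx:] < 1.0)
    if slope[mode_idx] < 1.0 or below.size == 0:
        warnings.warn(
            "CDF slope never crosses 1 above the mode; no high-tone periods"
        )
        return EmgToneMask(np.zeros(vals.size, dtype=bool), np.inf, rms.times,
                           slope_grid=grid + center, slope_values=slope)
    thr_z = grid[mode_idx + below[0]]
    threshold = thr_z + center
    mask = logr > threshold
    logger.info("EMG tone threshold = %.3f ln uV (%.1f uV); %.1f%% high",
                threshold, np.exp(threshold), 100 * mask.mean())
    return EmgToneMask(mask=mask, threshold_log_uv=float(threshold),
                       times=rms.times, slope_grid=grid + center,
                       slope_values=slope)


def emg_high_tone(x: np.ndarray, fs: float = 250.0, t0_s: float = 0.0) -> EmgToneMask:
    """Convenience chain: high-pass -> 1-s RMS -> slope threshold."""
    rms = emg_rms_series(highpass_emg(x, fs=fs), fs=fs, t0_s=t0_s)
    return high_tone_threshold(rms)
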