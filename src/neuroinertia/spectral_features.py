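"""Spectral features: multitaper window spectra, the 482-dim two-channel
feature vectors, PCA reduction and Bonferroni-corrected mean spectra.

Power is estimated on non-overlapping 4-s windows with Thomson multitapers
(time-bandwidth NW = 2, 3 tapers, i.e. half-bandwidth 0.5 Hz) and reported
on a fixed 241-bin grid, 0-120 Hz at 0.5 Hz spacing, so neighbouring bins
are approximately independent estimates.  Per window, the M2 and V1 log
spectra are expressed in dB relative to the mean log spectrum of the whole
recording set and concatenated to a 482-dim vector; PCA to 50 components
then provides the classifier feature space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.fft import rfft
from scipy import stats
from scipy.signal.windows import dpss
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "FREQ_GRID",
    "N_BINS_PER_CHANNEL",
    "SpectralWindowSet",
    "FeatureSet",
    "window_psd",
    "build_feature_matrix",
    "fit_pca",
    "project",
    "bonferroni_level",
    "mean_spectrum_with_ci",
]

#: 241 bin centers, 0-120 Hz inclusive at 0.5 Hz spacing
FREQ_GRID = np.arange(241) * 0.5
N_BINS_PER_CHANNEL = FREQ_GRID.size
REQUIRED_SOURCES = ("induction", "emergence", "emergence_induction_arm")

_TAPER_CACHE: dict = {}


def _tapers(n_samples: int, nw: float, k: int) -> np.ndarray:
    key = (n_samples, nw, k)
    if key not in _TAPER_CACHE:
        _TAPER_CACHE[key] = dpss(n_samples, nw, Kmax=k)  # unit-energy tapers
    return _TAPER_CACHE[key]


def window_psd(
    x: np.ndarray,
    fs: float = 250.0,
    window_s: float = 4.0,
    t0_s: float = 0.0,
    artifact_mask: np.ndarray | None = None,
    nw: float = 2.0,
    n_tapers: int = 3,
):
    """Multitaper PSD per non-overlapping window, on the 241-bin grid.

    Returns ``(psd, times)`` where ``psd`` is (n_windows, 241) in uV^2/Hz
    and ``times`` are window start times.  Windows flagged in
    ``artifact_mask`` are skipped; a segment shorter than one window yields
    zero windows.
    """
    x = np.asarray(x, dtype=float)
    n_win_samp = int(round(window_s * fs))
    n_win = x.size // n_win_samp
    times = t0_s + window_s * np.arange(n_win)
    if n_win == 0:
        return np.zeros((0, N_BINS_PER_CHANNEL)), times
    keep = np.ones(n_win, dtype=bool)
    if artifact_mask is not None:
        artifact_mask = np.asarray(artifact_mask, dtype=bool)
        if len(artifact_mask) != n_win:
            raise ValueError("artifact mask not aligned to the window grid")
        keep = ~artifact_mask
    xw = x[: n_win * n_win_samp].reshape(n_win, n_win_samp)[keep]
    tapers = _tapers(n_win_samp, nw, n_tapers)
    spec = rfft(xw[:, None, :] * tapers[None, :, :], n=n_win_samp, axis=-1)
    power = (2.0 / fs) * np.mean(np.abs(spec) ** 2, axis=1)
    power[:, 0] /= 2.0  # DC is not doubled in a one-sided spectrum
    # native resolution is fs/n = 0.25 Hz; take every other bin -> 0.5 Hz
    step = int(round(0.5 * n_win_samp / fs))
    psd = power[:, :: step][:, :N_BINS_PER_CHANNEL]
    return psd, times[keep]


@dataclass
class SpectralWindowSet:
    """Windows x 482 matrix of dB log-power differences from the set mean.

    Channel blocks are M2 (columns 0-240) then V1 (241-481); ``meta`` holds
    one row per window (source recording/arm and window time).
    """

    features: np.ndarray
    meta: pd.DataFrame
    mean_log_power_db: np.ndarray
    channel_names: tuple = ("M2", "V1")
    freqs_hz: np.ndarray = None

    def __post_init__(self):
        if self.freqs_hz is None:
            self.freqs_hz = FREQ_GRID
        if self.features.shape[1] != 2 * N_BINS_PER_CHANNEL:
            raise ValueError("features must have 482 columns (2 x 241 bins)")
        if len(self.meta) != self.features.shape[0]:
            raise ValueError("meta must have one row per window")

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]


def build_feature_matrix(sources: dict, eps: float = 1e-12) -> SpectralWindowSet:
    """Concatenate per-window M2/V1 log spectra and center on the set mean.

    ``sources`` maps source name -> dict with keys ``"M2"``, ``"V1"``
    (aligned (n, 241) PSD arrays) and ``"times"``.  All three canonical
    sources — the induction recording, the emergence arm, and the induction
    arm of the emergence recording — must be present, since the centering
    mean is defined over their union.
    """
    missing = [s for s in REQUIRED_SOURCES if s not in sources]
    if missing:
        raise ValueError(f"missing required source(s): {missing}")
    rows, meta_rows = [], []
    for name, data in sources.items():
        m2, v1, times = data["M2"], data["V1"], np.asarray(data["times"])
        if m2.shape != v1.shape or m2.shape[0] != times.size:
            raise ValueError(f"source {name!r}: M2/V1/time shapes disagree")
        feats = 10.0 * np.log10(np.maximum(np.concatenate([m2, v1], axis=1), eps))
        rows.append(feats)
        meta_rows.append(pd.DataFrame({"source": name, "time_s": times}))
    features = np.concatenate(rows, axis=0)
    mean_db = features.mean(axis=0)
    meta = pd.concat(meta_rows, ignore_index=True)
    return SpectralWindowSet(features=features - mean_db, meta=meta,
                             mean_log_power_db=mean_db)


@dataclass
class FeatureSet:
    """PCA-reduced window features: scores, loadings and variance fractions."""

    scores: np.ndarray                  # (n_windows, k)
    loadings: np.ndarray                # (482, k), orthonormal columns
    explained_variance_ratio: np.ndarray
    centering: np.ndarray               # (482,) training mean
    meta: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(windows: SpectralWindowSet, k: int = 50) -> FeatureSet:
    """Top-``k`` principal components of the feature covariance.

    Loadings are sign-fixed (largest-magnitude element positive) so outputs
    are reproducible across linear-algebra backends; if the matrix rank is
    below ``k`` the component count is reduced with a warning.
    """
    X = windows.features
    max_k = min(X.shape)
    if k > max_k:
        warnings.warn(f"rank limits PCA to {max_k} components (requested {k})")
        k = max_k
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # truncate at the effective rank (zero-variance directions carry no
    # signal and their loadings are arbitrary)
    tol = max(X.shape) * np.finfo(float).eps * pca.singular_values_.max()
    rank = int((pca.singular_values_ > tol).sum())
    if rank < k:
        warnings.warn(f"rank limits PCA to {rank} components (requested {k})")
        k = rank
        scores = scores[:, :k]
        pca.components_ = pca.components_[:k]
        pca.explained_variance_ratio_ = pca.explained_variance_ratio_[:k]
    loadings = pca.components_.T.copy()
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings *= flip
    scores = scores * flip
    return FeatureSet(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        centering=pca.mean_.copy(),
        meta=windows.meta.copy(),
    )


def project(feature_set: FeatureSet, new_features: np.ndarray) -> np.ndarray:
    """Project held-out 482-dim windows using the training centering/loadings."""
    return (np.asarray(new_features) - feature_set.centering) @ feature_set.loadings


def bonferroni_level(alpha: float = 0.05, n_comparisons: int = N_BINS_PER_CHANNEL) -> float:
    """Per-frequency CI level (percent) after Bonferroni correction.

    alpha = 0.05 over the 241 per-channel frequency bins gives 99.979%.
    """
    return 100.0 * (1.0 - alpha / n_comparisons)


def mean_spectrum_with_ci(
    log_power_db: np.ndarray,
    freqs_hz: np.ndarray = FREQ_GRID,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Mean log spectrum with simultaneous t-based confidence bands.

    ``log_power_db`` is (n_windows, n_freqs) for one channel/condition; the
    per-frequency two-sided CI is computed at level 1 - alpha/m (Bonferroni
    over the m frequency bins), reported in the ``level_percent`` column to
    three decimals.
    """
    X = np.asarray(log_power_db, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 windows per condition")
    m = X.shape[1] if n_comparisons is None else n_comparisons
    n = X.shape[0]
    mean = X.mean(axis=0)
    sem = X.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / m / 2.0, df=n - 1)
    half = tcrit * sem
    return pd.DataFrame({
        "frequency_hz": np.asarray(freqs_hz)[: X.shape[1]],
        "mean_db": mean,
        "ci_lo_db": mean - half,
        "ci_hi_db": mean + half,
        "level_percent": round(bonferroni_level(alpha, m), 3),
        "n_windows": n,
    })
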