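"""Magnitude-squared coherence spectra and band-averaged connectivity matrices.

The estimator realises the expectation in

    Coh2_ij(f) = |E[C_ij(f)]|^2 / (E[C_ii(f)] * E[C_jj(f)]),   C_ij = Y_i Y_j*

as an average over K overlapping tapered segments (Welch's method). With a
single segment the ratio is algebraically 1 for any pair of non-null series,
so configurations with K < 2 are rejected. The per-trial connectivity matrix
is the unweighted mean of Coh2 over the frequency bins inside the analysis
band (default 0.15-0.33 Hz), symmetric with zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import detrend as _sp_detrend
from scipy.signal import get_window

from .cohort import AcquisitionConfig, RoiTimeSeriesSet
from .errors import ConfigurationError, DegenerateInputError, InputError

__all__ = [
    "DEFAULT_BAND_HZ",
    "SpectralConfig",
    "CoherenceSpectrum",
    "ConnectivityMatrix",
    "cross_spectral_density",
    "coherence_spectrum",
    "band_average",
    "connectivity_matrix",
]

#: Analysis band over which coherence is averaged (Hz), inclusive bounds.
DEFAULT_BAND_HZ: tuple[float, float] = (0.15, 0.33)

_BAND_TOL = 1e-9  # float tolerance when testing band membership


@dataclass(frozen=True)
class SpectralConfig:
    """Welch segmentation parameters.

    The defaults (64-sample Hann segments, 50% overlap, per-segment mean
    removal) give K = 7 segments on a 258-sample trial and a grid step of
    1/(64 x 1.5 s) ~ 0.0104 Hz.
    """

    segment_length: int = 64
    overlap_fraction: float = 0.5
    window: str = "hann"
    detrend: str = "mean"

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ConfigurationError("segment_length must be at least 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ConfigurationError("overlap_fraction must lie in [0, 1)")
        if self.detrend not in ("none", "mean", "linear"):
            raise ConfigurationError("detrend must be one of none/mean/linear")

    @property
    def step(self) -> int:
        step = self.segment_length - int(self.overlap_fraction * self.segment_length)
        return max(step, 1)

    def n_segments(self, n_samples: int) -> int:
        if n_samples < self.segment_length:
            raise ConfigurationError("segment_length exceeds series length")
        return (n_samples - self.segment_length) // self.step + 1

    def require_averaging(self, n_samples: int) -> int:
        """Segment count K, rejecting the degenerate K = 1 estimator."""
        k = self.n_segments(n_samples)
        if k < 2:
            raise ConfigurationError(
                "Welch averaging needs K >= 2 segments; with K = 1 the "
                "coherence estimator is identically 1"
            )
        return k


def _segment_ffts(x: np.ndarray, cfg: SpectralConfig) -> np.ndarray:
    """One-sided rFFT of each detrended, tapered segment; shape (K, n_bins)."""
    seg, step = cfg.segment_length, cfg.step
    k = cfg.require_averaging(len(x))
    win = get_window(cfg.window, seg)
    starts = np.arange(k) * step
    segments = np.stack([x[s : s + seg] for s in starts]).astype(float)
    if cfg.detrend == "mean":
        segments = segments - segments.mean(axis=1, keepdims=True)
    elif cfg.detrend == "linear":
        segments = _sp_detrend(segments, axis=1, type="linear")
    if np.any(segments.std(axis=1) == 0.0):
        raise DegenerateInputError("zero-variance segment: coherence undefined")
    return np.fft.rfft(segments * win, axis=1)


def _csd_from_ffts(
    fx: np.ndarray, fy: np.ndarray, cfg: SpectralConfig, acq: AcquisitionConfig
) -> np.ndarray:
    """Segment-averaged one-sided cross-spectral density C_xy = E[X Y*]."""
    win = get_window(cfg.window, cfg.segment_length)
    scale = 1.0 / (acq.sampling_freq_hz * np.sum(win**2))
    csd = (fx * np.conj(fy)).mean(axis=0) * scale
    # one-sided density: double interior bins (not DC; not Nyquist when the
    # segment length is even and the last bin sits exactly at Nyquist)
    csd[1:] *= 2.0
    if cfg.segment_length % 2 == 0:
        csd[-1] /= 2.0
    return csd


def _grid(cfg: SpectralConfig, acq: AcquisitionConfig) -> np.ndarray:
    return np.fft.rfftfreq(cfg.segment_length, d=acq.tr_seconds)


def _check_lengths(x: np.ndarray, y: np.ndarray, acq: AcquisitionConfig) -> None:
    if len(x) != len(y):
        raise InputError(f"series lengths differ: {len(x)} vs {len(y)}")
    if len(x) != acq.n_samples:
        raise InputError(
            f"series length {len(x)} does not match acquisition n_samples "
            f"{acq.n_samples}"
        )


def cross_spectral_density(
    x: np.ndarray,
    y: np.ndarray,
    cfg: SpectralConfig | None = None,
    acq: AcquisitionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch estimate of the one-sided cross-spectral density of (x, y).

    Returns ``(freqs_hz, csd)`` with ``csd(x, y) = conj(csd(y, x))``
    bin-for-bin and ``csd(x, x)`` real and nonnegative.
    """
    cfg = cfg or SpectralConfig()
    acq = acq or AcquisitionConfig()
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_lengths(x, y, acq)
    fx = _segment_ffts(x, cfg)
    fy = fx if y is x or np.array_equal(x, y) else _segment_ffts(y, cfg)
    return _grid(cfg, acq), _csd_from_ffts(fx, fy, cfg, acq)


@dataclass(frozen=True, eq=False)
class CoherenceSpectrum:
    """Coh2 of one ROI pair on the estimator grid (DC bin excluded)."""

    pair: tuple[str, str]
    freqs_hz: np.ndarray
    coh2: np.ndarray

    def __post_init__(self) -> None:
        if self.freqs_hz.shape != self.coh2.shape:
            raise InputError("freqs_hz and coh2 must have equal shape")
        if np.any(self.coh2 < 0) or np.any(self.coh2 > 1):
            raise InputError("coherence values must lie in [0, 1]")


def coherence_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    cfg: SpectralConfig | None = None,
    acq: AcquisitionConfig | None = None,
    pair: tuple[str, str] = ("x", "y"),
) -> CoherenceSpectrum:
    """Magnitude-squared coherence of (x, y) per frequency bin.

    Values are clipped into [0, 1] only against floating-point overshoot
    (tolerance 1e-12); the estimator is bounded by construction.
    """
    cfg = cfg or SpectralConfig()
    acq = acq or AcquisitionConfig()
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_lengths(x, y, acq)
    fx = _segment_ffts(x, cfg)
    fy = fx if np.array_equal(x, y) else _segment_ffts(y, cfg)
    pxy = (fx * np.conj(fy)).mean(axis=0)
    pxx = (np.abs(fx) ** 2).mean(axis=0)
    pyy = (np.abs(fy) ** 2).mean(axis=0)
    freqs = _grid(cfg, acq)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh2 = np.abs(pxy) ** 2 / (pxx * pyy)
    coh2 = np.where((pxx == 0) | (pyy == 0), 0.0, coh2)
    if np.any(coh2 > 1.0 + 1e-12) or np.any(coh2 < -1e-12):
        raise InputError("coherence estimate escaped [0, 1] beyond float tolerance")
    coh2 = np.clip(coh2, 0.0, 1.0)
    # drop the DC bin: mean removal voids it and no band may include it
    return CoherenceSpectrum(pair=pair, freqs_hz=freqs[1:], coh2=coh2[1:])


def band_average(spec: CoherenceSpectrum, band_hz: tuple[float, float]) -> float:
    """Unweighted mean of Coh2 over grid bins with low <= f <= high."""
    low, high = band_hz
    if not low < high:
        raise ConfigurationError("band must satisfy low < high")
    mask = (spec.freqs_hz >= low - _BAND_TOL) & (spec.freqs_hz <= high + _BAND_TOL)
    if not mask.any():
        raise ConfigurationError(
            f"no frequency bins inside band [{low}, {high}] Hz "
            f"(grid step {spec.freqs_hz[0]:.4g} Hz)"
        )
    return float(spec.coh2[mask].mean())


@dataclass(frozen=True, eq=False)
class ConnectivityMatrix:
    """Symmetric zero-diagonal matrix of band-averaged coherences."""

    values: np.ndarray
    roi_labels: tuple[str, ...]
    band_hz: tuple[float, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        n = len(self.roi_labels)
        if self.values.shape != (n, n):
            raise InputError("matrix shape must match ROI label count")
        if not np.allclose(self.values, self.values.T):
            raise InputError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InputError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise InputError("connectivity values must be nonnegative")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def offdiag_pairs(self) -> list[tuple[str, str]]:
        """The unique ROI pairs (upper triangle), row-order."""
        return [
            (self.roi_labels[i], self.roi_labels[j])
            for i in range(self.n_rois)
            for j in range(i + 1, self.n_rois)
        ]

    def offdiag_values(self) -> np.ndarray:
        """The unique off-diagonal entries (upper triangle), row-order."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.values[iu]

    def entry(self, roi_a: str, roi_b: str) -> float:
        try:
            ia = self.roi_labels.index(roi_a)
            ib = self.roi_labels.index(roi_b)
        except ValueError as exc:
            raise InputError(f"unknown ROI in pair ({roi_a}, {roi_b})") from exc
        return float(self.values[ia, ib])

    def with_values(self, values: np.ndarray, normalized: bool) -> "ConnectivityMatrix":
        return replace(self, values=values, normalized=normalized)


def connectivity_matrix(
    ts: RoiTimeSeriesSet,
    cfg: SpectralConfig | None = None,
    acq: AcquisitionConfig | None = None,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    roi_labels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Band-averaged coherence matrix over the analysis ROIs of one trial.

    The control ROI (UNR) is excluded by default: it enters only the
    feedback-signal computation, never the connectivity analysis. Segment
    FFTs are computed once per ROI and reused across the 15 pairs.
    """
    from .cohort import CONTROL_ROI  # local import to avoid cycle at module load

    cfg = cfg or SpectralConfig()
    acq = acq or AcquisitionConfig()
    if roi_labels is None:
        roi_labels = tuple(l for l in ts.roi_labels if l != CONTROL_ROI)
    else:
        roi_labels = tuple(roi_labels)
    missing = [l for l in roi_labels if l not in ts.roi_labels]
    if missing:
        raise InputError(f"ROIs missing from time series: {missing}")
    if ts.n_samples != acq.n_samples:
        raise InputError("time-series length does not match acquisition")
    ffts = {l: _segment_ffts(ts.series(l), cfg) for l in roi_labels}
    freqs = _grid(cfg, acq)[1:]
    low, high = band_hz
    mask = (freqs >= low - _BAND_TOL) & (freqs <= high + _BAND_TOL)
    if not mask.any():
        raise ConfigurationError(f"no frequency bins inside band [{low}, {high}] Hz")
    n = len(roi_labels)
    auto = {l: (np.abs(f) ** 2).mean(axis=0)[1:] for l, f in ffts.items()}
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            li, lj = roi_labels[i], roi_labels[j]
            pxy = (ffts[li] * np.conj(ffts[lj])).mean(axis=0)[1:]
            coh2 = np.clip(np.abs(pxy) ** 2 / (auto[li] * auto[lj]), 0.0, 1.0)
            values[i, j] = values[j, i] = coh2[mask].mean()
    return ConnectivityMatrix(
        values=values, roi_labels=roi_labels, band_hz=(low, high), normalized=False
    )
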