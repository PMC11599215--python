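"""Detrended cross-correlation coupling estimators.

This module implements the detrended cross-correlation coefficient (DCCC) at a
single window length (scale), its multiscale extension MDC3 — a Fisher-z
weighted average of DCCC over scales with weights taken from the relative
cross-spectral power of the corresponding frequencies — and the directed
variant dMDC3, in which the per-window covariance is replaced by the
maximum-absolute lagged covariance, computed separately for negative lags
(first signal leading) and positive lags (first signal lagging).

Two baseline estimators are provided for benchmarking: the ordinary Pearson
product-moment correlation and the global lagged covariance (LG), i.e. the
signed maximum-absolute covariance over all lags of the globally detrended
signals, without variance normalization.

Scales are derived from analysis frequencies through the sampling rate,
``s = round(SR / f)``, so the user chooses a frequency band rather than an
arbitrary set of window lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .exceptions import (
    DegenerateSignalError,
    DegenerateWindowError,
    InvalidInputError,
    InvalidParameterError,
    InvalidScaleError,
    NoValidScalesError,
)

__all__ = [
    "TimeSeries",
    "FrequencyGrid",
    "DetrendConfig",
    "DCCCProfile",
    "CouplingResult",
    "partition_windows",
    "polynomial_detrend",
    "dccc_at_scale",
    "spectral_weights",
    "dccc_profile",
    "mdc3",
    "windowed_lagged_covariance",
    "dmdc3",
    "pearson_r",
    "global_lagged_covariance",
]

logger = logging.getLogger(__name__)

# Fisher's z transform diverges at +/-1; DCCC values are clipped this far
# inside the open interval before atanh.
FISHER_CLIP = 1e-12

#: Minimum window length: every window must contain at least 8 samples.
MIN_SCALE = 8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled univariate signal.

    Parameters
    ----------
    values : array-like of float
        Signal samples, length >= 2, all finite.
    sampling_rate : float
        Sampling rate in Hz, strictly positive.
    """

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise InvalidInputError(
                f"a time series must be a 1-D sequence of length >= 2, "
                f"got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("time series contains non-finite values")
        if not (self.sampling_rate > 0):
            raise InvalidParameterError(
                f"sampling_rate must be positive, got {self.sampling_rate}"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FrequencyGrid:
    """Analysis frequencies and their conversion to integer scales.

    The grid covers ``f_min, f_min + f_step, ...`` up to ``f_max`` inclusive.
    Each frequency ``f`` maps to the window length ``s = round(sampling_rate/f)``.
    Every scale must hold at least :data:`MIN_SCALE` samples, which bounds
    ``f_max`` from above (well below Nyquist in practice).
    """

    f_min: float
    f_max: float
    f_step: float
    sampling_rate: float

    def __post_init__(self) -> None:
        if not (0 < self.f_min <= self.f_max):
            raise InvalidParameterError(
                f"need 0 < f_min <= f_max, got f_min={self.f_min}, f_max={self.f_max}"
            )
        if not (self.f_step > 0):
            raise InvalidParameterError(f"f_step must be positive, got {self.f_step}")
        if not (self.f_max < self.sampling_rate / 2):
            raise InvalidParameterError(
                f"f_max={self.f_max} must lie below the Nyquist frequency "
                f"{self.sampling_rate / 2}"
            )
        if self.scales.min() < MIN_SCALE:
            raise InvalidParameterError(
                f"highest frequency {self.f_max} maps to a window of "
                f"{self.scales.min()} samples; at least {MIN_SCALE} are required"
            )

    @property
    def frequencies(self) -> np.ndarray:
        """Requested frequencies in Hz (inclusive of f_max up to rounding)."""
        n = int(np.floor((self.f_max - self.f_min) / self.f_step + 1e-9)) + 1
        return self.f_min + self.f_step * np.arange(n)

    @property
    def scales(self) -> np.ndarray:
        """Integer window length per frequency, ``round(sampling_rate / f)``."""
        return np.rint(self.sampling_rate / self.frequencies).astype(int)


@dataclass(frozen=True)
class DetrendConfig:
    """Detrending and estimator options.

    Parameters
    ----------
    degree : int
        Order of the least-squares polynomial removed in every window (and
        from the whole signal before spectral weighting). Default 2; windows
        must contain at least ``degree + 2`` samples.
    welch_nperseg : int, optional
        If set, the cross-spectral density for the weights is estimated by
        Welch averaging with this segment length instead of the single
        whole-signal cross-periodogram (the default).
    integrate : bool
        If True, cumulatively sum both signals before estimation. Off by
        default: integration adds non-stationarity and degrades accuracy; the
        flag exists to reproduce that comparison.
    """

    degree: int = 2
    welch_nperseg: int | None = None
    integrate: bool = False

    def __post_init__(self) -> None:
        if self.degree < 0 or int(self.degree) != self.degree:
            raise InvalidParameterError(
                f"degree must be a nonnegative integer, got {self.degree}"
            )
        if self.welch_nperseg is not None and self.welch_nperseg < 2:
            raise InvalidParameterError("welch_nperseg must be >= 2")


@dataclass(frozen=True)
class DCCCProfile:
    """Per-frequency DCCC values and the spectral weights used by MDC3.

    Frequencies mapping to the same integer scale share one computed DCCC
    value but keep their individual spectral weights. Weights sum to 1 over
    the retained frequencies.
    """

    frequencies: np.ndarray
    scales: np.ndarray
    dccc_values: np.ndarray
    weights: np.ndarray
    dropped_frequencies: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass(frozen=True)
class CouplingResult:
    """Outcome of a coupling estimation.

    Undirected estimators fill ``value``; directed estimators fill
    ``leading`` and ``lagging`` (``leading`` quantifies the first signal
    driving the second).
    """

    value: float | None = None
    leading: float | None = None
    lagging: float | None = None
    n_frequencies_used: int = 0
    dropped_frequencies: tuple = ()

    @property
    def directed(self) -> bool:
        return self.value is None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_values(x) -> np.ndarray:
    if isinstance(x, TimeSeries):
        return x.values
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"expected a 1-D sequence, got shape {arr.shape}")
    return arr


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xv, yv = _as_values(x), _as_values(y)
    if xv.size != yv.size:
        raise InvalidInputError(
            f"signals must have equal length, got {xv.size} and {yv.size}"
        )
    return xv, yv


def _detrend_matrix(windows: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares polynomial detrend of every row of ``windows``.

    Rows are windows of equal length s; the fit is against the sample index
    0..s-1. Uses one pseudoinverse of the Vandermonde matrix for all rows.
    """
    s = windows.shape[-1]
    if s < degree + 2:
        raise DegenerateWindowError(
            f"window of {s} samples cannot be detrended with degree {degree} "
            f"(needs >= {degree + 2})"
        )
    t = np.arange(s, dtype=float)
    # scale index to [0, 1] for conditioning; the fitted subspace is identical
    vand = np.vander(t / max(s - 1, 1), degree + 1, increasing=True)
    coefs = windows @ np.linalg.pinv(vand).T
    return windows - coefs @ vand.T


def _maybe_integrate(xv: np.ndarray, yv: np.ndarray, cfg: DetrendConfig):
    if cfg.integrate:
        return np.cumsum(xv), np.cumsum(yv)
    return xv, yv


# ---------------------------------------------------------------------------
# windowing and detrending
# ---------------------------------------------------------------------------


def partition_windows(x, s: int) -> np.ndarray:
    """Split a signal into consecutive non-overlapping windows of length ``s``.

    Returns an ``(N, s)`` array with ``N = floor(len(x) / s)``; the trailing
    remainder (``len(x) mod s`` samples) is discarded. Windows start at
    sample 0.
    """
    xv = _as_values(x)
    s = int(s)
    if s < 1:
        raise InvalidScaleError(f"scale must be >= 1, got {s}")
    if s > xv.size:
        raise InvalidScaleError(
            f"scale {s} exceeds signal length {xv.size}"
        )
    n = xv.size // s
    return xv[: n * s].reshape(n, s)


def polynomial_detrend(segment, degree: int) -> np.ndarray:
    """Residuals of a least-squares polynomial fit against the sample index."""
    seg = _as_values(segment)
    return _detrend_matrix(seg[None, :], degree)[0]


# ---------------------------------------------------------------------------
# DCCC / MDC3
# ---------------------------------------------------------------------------


def _window_moments(xv, yv, s, degree):
    """Detrended per-window residual matrices plus pooled variances."""
    xh = _detrend_matrix(partition_windows(xv, s), degree)
    yh = _detrend_matrix(partition_windows(yv, s), degree)
    var_x = np.mean(xh * xh, axis=1)  # population divisor s, consistently
    var_y = np.mean(yh * yh, axis=1)
    return xh, yh, var_x, var_y


def dccc_at_scale(x, y, s: int, cfg: DetrendConfig = DetrendConfig()) -> float:
    """Detrended cross-correlation coefficient at one window length.

    The signals are cut into non-overlapping windows of length ``s``, each
    window is polynomially detrended, and the coefficient is the ratio of the
    window-averaged covariance to the geometric mean of the window-averaged
    variances. Lies in [-1, 1] by Cauchy-Schwarz.
    """
    xv, yv = _check_pair(x, y)
    xv, yv = _maybe_integrate(xv, yv, cfg)
    xh, yh, var_x, var_y = _window_moments(xv, yv, s, cfg.degree)
    denom = np.sqrt(var_x.mean() * var_y.mean())
    if denom == 0:
        raise DegenerateSignalError(
            f"zero pooled detrended variance at scale {s}; DCCC is undefined"
        )
    cov = np.mean(xh * yh, axis=1)
    return float(cov.mean() / denom)


def _csd_magnitude(xd: np.ndarray, yd: np.ndarray, sr: float,
                   cfg: DetrendConfig) -> tuple[np.ndarray, np.ndarray]:
    """One-sided cross-spectral magnitude of the already-detrended pair."""
    if cfg.welch_nperseg is not None:
        nperseg = min(cfg.welch_nperseg, xd.size)
        freqs, csd = _signal.csd(xd, yd, fs=sr, nperseg=nperseg)
        return freqs, np.abs(csd)
    # whole-signal cross-periodogram; only relative magnitudes matter. The
    # real/imaginary parts are assembled so the magnitude is bitwise
    # symmetric in the pair, keeping mdc3(x,y) == mdc3(y,x) exactly.
    freqs = np.fft.rfftfreq(xd.size, d=1.0 / sr)
    fx = np.fft.rfft(xd)
    fy = np.fft.rfft(yd)
    re = fx.real * fy.real + fx.imag * fy.imag
    im = fx.imag * fy.real - fx.real * fy.imag
    return freqs, np.hypot(re, im)


def _valid_scale_mask(grid: FrequencyGrid, n: int, degree: int) -> np.ndarray:
    scales = grid.scales
    return (scales <= n) & (scales >= degree + 2)


def spectral_weights(x, y, grid: FrequencyGrid,
                     cfg: DetrendConfig = DetrendConfig()) -> np.ndarray:
    """Relative cross-spectral power at each requested frequency.

    Both signals are detrended as a whole (polynomial of ``cfg.degree``), the
    one-sided cross-spectral density magnitude is computed, and each requested
    frequency reads the nearest spectral bin. Weights are normalized to sum
    to 1 over the frequencies whose scale is valid for this signal length;
    dropped frequencies get weight 0.
    """
    xv, yv = _check_pair(x, y)
    xv, yv = _maybe_integrate(xv, yv, cfg)
    sr = grid.sampling_rate
    valid = _valid_scale_mask(grid, xv.size, cfg.degree)
    if not valid.any():
        raise NoValidScalesError(
            f"no requested frequency yields a usable scale for signals of "
            f"length {xv.size}"
        )
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning(
            "dropped %d of %d requested frequencies (scale invalid for "
            "signal length %d)", n_dropped, valid.size, xv.size,
        )
    xd = polynomial_detrend(xv, cfg.degree)
    yd = polynomial_detrend(yv, cfg.degree)
    freqs_bins, mag = _csd_magnitude(xd, yd, sr, cfg)
    requested = grid.frequencies
    idx = np.abs(freqs_bins[None, :] - requested[:, None]).argmin(axis=1)
    weights = np.where(valid, mag[idx], 0.0)
    total = weights.sum()
    if total == 0:
        # flat-zero cross-spectrum (e.g. orthogonal pure tones): fall back to
        # uniform weights over the retained frequencies
        weights = valid.astype(float)
        total = weights.sum()
    return weights / total


def dccc_profile(x, y, grid: FrequencyGrid,
                 cfg: DetrendConfig = DetrendConfig()) -> DCCCProfile:
    """DCCC per retained frequency plus the spectral weights.

    Frequencies that map to the same integer scale share one DCCC value.
    """
    xv, yv = _check_pair(x, y)
    weights_full = spectral_weights(xv, yv, grid, cfg)  # handles integrate via cfg
    xv, yv = _maybe_integrate(xv, yv, cfg)
    valid = _valid_scale_mask(grid, xv.size, cfg.degree)
    freqs = grid.frequencies[valid]
    scales = grid.scales[valid]
    weights = weights_full[valid]
    dccc_by_scale = {
        s: dccc_at_scale(xv, yv, s, DetrendConfig(degree=cfg.degree))
        for s in np.unique(scales)
    }
    values = np.array([dccc_by_scale[s] for s in scales])
    return DCCCProfile(
        frequencies=freqs,
        scales=scales,
        dccc_values=values,
        weights=weights,
        dropped_frequencies=grid.frequencies[~valid],
    )


def _fisher_combine(values: np.ndarray, weights: np.ndarray) -> float:
    z = np.arctanh(np.clip(values, -1 + FISHER_CLIP, 1 - FISHER_CLIP))
    return float(np.tanh(np.sum(weights * z)))


def mdc3(x, y, grid: FrequencyGrid,
         cfg: DetrendConfig = DetrendConfig()) -> CouplingResult:
    """Multiscale detrended cross-correlation coefficient.

    DCCC is computed at the scale of every retained frequency, Fisher
    z-transformed, averaged with the spectral weights, and mapped back with
    tanh. Symmetric in its two arguments; the result lies in (-1, 1).
    """
    profile = dccc_profile(x, y, grid, cfg)
    value = _fisher_combine(profile.dccc_values, profile.weights)
    return CouplingResult(
        value=value,
        n_frequencies_used=profile.frequencies.size,
        dropped_frequencies=tuple(profile.dropped_frequencies),
    )


# ---------------------------------------------------------------------------
# directed estimators
# ---------------------------------------------------------------------------

#: A lagged covariance is only evaluated where the two shifted windows share
#: at least this many samples.
MIN_LAG_OVERLAP = 2


def _lagged_cov_table(xhat: np.ndarray, yhat: np.ndarray):
    """Covariance of ``xhat`` shifted by each lag against ``yhat``.

    Lag ``k`` pairs ``xhat[t + k]`` with ``yhat[t]`` over the overlapping
    samples, divisor = overlap length; negative lags therefore align earlier
    samples of ``xhat`` with current ``yhat`` (first signal leading).
    """
    s = xhat.size
    lags = np.arange(-(s - 1), s)
    overlap = s - np.abs(lags)
    cov = np.correlate(xhat, yhat, mode="full") / overlap
    return lags, overlap, cov


def windowed_lagged_covariance(xhat, yhat, direction: str) -> float:
    """Signed maximum-absolute lagged covariance in one direction.

    ``direction='leading'`` scans negative lags (first signal leads),
    ``'lagging'`` scans positive lags. Lags with fewer than
    :data:`MIN_LAG_OVERLAP` overlapping samples are excluded. Ties in |cov|
    are broken toward the smaller |lag|, then the negative lag.
    """
    xh, yh = _check_pair(xhat, yhat)
    s = xh.size
    if s < 2:
        raise InvalidScaleError(f"lagged covariance needs a window of >= 2, got {s}")
    if direction not in ("leading", "lagging"):
        raise InvalidParameterError(
            f"direction must be 'leading' or 'lagging', got {direction!r}"
        )
    lags, overlap, cov = _lagged_cov_table(xh, yh)
    if direction == "leading":
        keep = (lags < 0) & (overlap >= MIN_LAG_OVERLAP)
    else:
        keep = (lags > 0) & (overlap >= MIN_LAG_OVERLAP)
    if not keep.any():
        raise InvalidScaleError(
            f"no lag with overlap >= {MIN_LAG_OVERLAP} in direction {direction}"
        )
    lags, cov = lags[keep], cov[keep]
    best = np.abs(cov).max()
    ties = np.flatnonzero(np.abs(cov) == best)
    # smaller |lag| first, then negative lag
    order = ties[np.lexsort((lags[ties], np.abs(lags[ties])))]
    return float(cov[order[0]])


def dmdc3(x, y, grid: FrequencyGrid,
          cfg: DetrendConfig = DetrendConfig()) -> CouplingResult:
    """Directed MDC3: per-window covariance replaced by lagged covariance.

    For each window the numerator becomes the signed maximum-absolute lagged
    covariance, evaluated separately over negative lags (``x`` leading) and
    positive lags (``x`` lagging); the variance normalization and spectral
    weighting are unchanged. Returns a (leading, lagging) pair;
    ``dmdc3(x, y).leading == dmdc3(y, x).lagging`` by construction.
    """
    xv, yv = _check_pair(x, y)
    weights_full = spectral_weights(xv, yv, grid, cfg)
    xv, yv = _maybe_integrate(xv, yv, cfg)
    valid = _valid_scale_mask(grid, xv.size, cfg.degree)
    scales = grid.scales[valid]
    weights = weights_full[valid]
    ratios: dict[int, tuple[float, float]] = {}
    for s in np.unique(scales):
        xh, yh, var_x, var_y = _window_moments(xv, yv, int(s), cfg.degree)
        denom = np.sqrt(var_x.mean() * var_y.mean())
        if denom == 0:
            raise DegenerateSignalError(
                f"zero pooled detrended variance at scale {s}"
            )
        lead = np.mean(
            [windowed_lagged_covariance(a, b, "leading") for a, b in zip(xh, yh)]
        )
        lag = np.mean(
            [windowed_lagged_covariance(a, b, "lagging") for a, b in zip(xh, yh)]
        )
        ratios[int(s)] = (lead / denom, lag / denom)
    lead_vals = np.array([ratios[int(s)][0] for s in scales])
    lag_vals = np.array([ratios[int(s)][1] for s in scales])
    return CouplingResult(
        leading=_fisher_combine(lead_vals, weights),
        lagging=_fisher_combine(lag_vals, weights),
        n_frequencies_used=int(valid.sum()),
        dropped_frequencies=tuple(grid.frequencies[~valid]),
    )


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of the raw signals."""
    xv, yv = _check_pair(x, y)
    if xv.size < 2:
        raise InvalidInputError("pearson_r needs at least 2 samples")
    if np.var(xv) == 0 or np.var(yv) == 0:
        raise DegenerateSignalError("zero variance; Pearson r is undefined")
    return float(np.corrcoef(xv, yv)[0, 1])


def global_lagged_covariance(x, y,
                             cfg: DetrendConfig = DetrendConfig()) -> CouplingResult:
    """Lagged-covariance (LG) baseline: whole signal as a single window.

    Both signals are globally detrended and the signed maximum-absolute
    covariance is taken per direction over all lags up to +/-(L-1). The
    result is unnormalized (no variance division); Z-scoring happens at the
    matrix level downstream.
    """
    xv, yv = _check_pair(x, y)
    xv, yv = _maybe_integrate(xv, yv, cfg)
    xd = polynomial_detrend(xv, cfg.degree)
    yd = polynomial_detrend(yv, cfg.degree)
    return CouplingResult(
        leading=windowed_lagged_covariance(xd, yd, "leading"),
        lagging=windowed_lagged_covariance(xd, yd, "lagging"),
    )
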