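"""Coupled ARFIMA(0, d, 0) ground-truth simulation.

Fractionally integrated noise written as a truncated moving average of
Gaussian innovations,

    A_t = sum_{n=0}^{order} alpha_n(d) * eps_{A, t-n},
    alpha_n(d) = Gamma(n + d) / (Gamma(n + 1) * Gamma(d)),

with a second channel sharing correlated innovations

    eps_B = rho * eps_A + eps * sqrt(1 - rho^2),

so the pair carries a known innovation cross-correlation ``rho``. The
fractional-integration parameter ``d`` controls long memory: ``d < 0.5``
yields (weakly) stationary series, ``d >= 0.5`` non-stationary ones.

Two regimes bundle the sampling rate and analysis band used downstream:
``eeg_meg`` (250 Hz, 0.5-31 Hz in steps of 0.5) and ``fmri`` (1 Hz,
0.01-0.12 Hz in steps of 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core import FrequencyGrid, TimeSeries
from .exceptions import InvalidParameterError

__all__ = [
    "ARFIMAConfig",
    "REGIMES",
    "arfima_coefficients",
    "coupled_innovations",
    "simulate_pair",
    "simulate_delayed_pair",
]

#: regime name -> (sampling rate Hz, (f_min, f_max, f_step) in Hz)
REGIMES: dict[str, tuple[float, tuple[float, float, float]]] = {
    "eeg_meg": (250.0, (0.5, 31.0, 0.5)),
    "fmri": (1.0, (0.01, 0.12, 0.01)),
}


@dataclass(frozen=True)
class ARFIMAConfig:
    """Parameters of one simulated coupled pair.

    Parameters
    ----------
    d : float
        Fractional-integration parameter, > 0. Values below 0.5 give
        stationary series, values at or above 0.5 non-stationary ones.
    rho : float
        Injected innovation cross-correlation, in [-1, 1].
    length : int
        Output samples per channel, >= 8.
    truncation_order : int
        Number of moving-average terms beyond lag 0 (kernel length is
        ``truncation_order + 1``). Default 100.
    seed : int
        Master seed of the pair.
    regime : str
        ``'eeg_meg'`` or ``'fmri'``; fixes sampling rate and analysis band.
    """

    d: float
    rho: float
    length: int
    truncation_order: int = 100
    seed: int = 0
    regime: str = "eeg_meg"

    def __post_init__(self) -> None:
        if not (self.d > 0):
            raise InvalidParameterError(f"d must be > 0, got {self.d}")
        if not (-1 <= self.rho <= 1):
            raise InvalidParameterError(f"|rho| must be <= 1, got {self.rho}")
        if self.length < 8:
            raise InvalidParameterError(f"length must be >= 8, got {self.length}")
        if self.truncation_order < 1:
            raise InvalidParameterError(
                f"truncation_order must be >= 1, got {self.truncation_order}"
            )
        if self.regime not in REGIMES:
            raise InvalidParameterError(
                f"regime must be one of {sorted(REGIMES)}, got {self.regime!r}"
            )

    @property
    def sampling_rate(self) -> float:
        return REGIMES[self.regime][0]

    @property
    def is_stationary(self) -> bool:
        return self.d < 0.5

    def frequency_grid(self) -> FrequencyGrid:
        """The regime's default analysis grid."""
        f_min, f_max, f_step = REGIMES[self.regime][1]
        return FrequencyGrid(f_min, f_max, f_step, self.sampling_rate)


def arfima_coefficients(d: float, order: int) -> np.ndarray:
    """Moving-average weights alpha_0..alpha_order of fractional integration.

    Computed in log-gamma space, so large ``d`` and ``order`` do not overflow
    intermediate Gamma ratios. alpha_0 = 1 and alpha_1 = d analytically.
    """
    if not (d > 0):
        raise InvalidParameterError(f"d must be > 0, got {d}")
    if order < 0:
        raise InvalidParameterError(f"order must be >= 0, got {order}")
    n = np.arange(order + 1, dtype=float)
    return np.exp(gammaln(n + d) - gammaln(n + 1) - gammaln(d))


def coupled_innovations(n: int, rho: float,
                        seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal innovation streams with correlation ``rho``.

    ``eps_A`` and an independent ``eps`` are drawn in that order from one
    seeded generator; ``eps_B = rho * eps_A + eps * sqrt(1 - rho^2)`` has unit
    variance and correlation ``rho`` with ``eps_A``.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if not (-1 <= rho <= 1):
        raise InvalidParameterError(f"|rho| must be <= 1, got {rho}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps_a = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    if rho == 1:
        eps_b = eps_a.copy()
    elif rho == -1:
        eps_b = -eps_a
    else:
        eps_b = rho * eps_a + eps * np.sqrt(1.0 - rho * rho)
    return eps_a, eps_b


def _convolve_kernel(eps: np.ndarray, coeffs: np.ndarray, length: int) -> np.ndarray:
    # 'valid' keeps only samples with a complete kernel history (burn-in)
    out = np.convolve(eps, coeffs, mode="valid")
    assert out.size == length
    return out


def simulate_pair(cfg: ARFIMAConfig) -> tuple[TimeSeries, TimeSeries]:
    """Simulate one coupled ARFIMA(0, d, 0) pair.

    ``length + truncation_order`` innovations are drawn per channel so every
    output sample is a full convolution with the ``truncation_order + 1``-term
    kernel (no partially initialized edge samples). Bit-reproducible from the
    config, including the seed.
    """
    coeffs = arfima_coefficients(cfg.d, cfg.truncation_order)
    n_inno = cfg.length + cfg.truncation_order
    eps_a, eps_b = coupled_innovations(n_inno, cfg.rho, cfg.seed)
    a = _convolve_kernel(eps_a, coeffs, cfg.length)
    b = _convolve_kernel(eps_b, coeffs, cfg.length)
    sr = cfg.sampling_rate
    return TimeSeries(a, sr), TimeSeries(b, sr)


def simulate_delayed_pair(cfg: ARFIMAConfig, delay: int) -> tuple[TimeSeries, TimeSeries]:
    """Coupled pair in which the second channel trails the first by ``delay``.

    The innovation coupling becomes ``eps_B,t = rho * eps_A,t-delay +
    eps_t * sqrt(1 - rho^2)``, a directed (effective) connection from A to B
    with a known lag in samples. ``delay = 0`` reduces to
    :func:`simulate_pair`.
    """
    if delay < 0 or int(delay) != delay:
        raise InvalidParameterError(f"delay must be a nonnegative integer, got {delay}")
    delay = int(delay)
    coeffs = arfima_coefficients(cfg.d, cfg.truncation_order)
    n_inno = cfg.length + cfg.truncation_order
    rng = np.random.default_rng(cfg.seed)
    eps_a_full = rng.standard_normal(n_inno + delay)
    eps_ind = rng.standard_normal(n_inno)
    eps_a = eps_a_full[delay:]  # channel A runs `delay` samples ahead
    if abs(cfg.rho) == 1:
        eps_b = np.sign(cfg.rho) * eps_a_full[:n_inno]
    else:
        eps_b = cfg.rho * eps_a_full[:n_inno] + np.sqrt(1.0 - cfg.rho**2) * eps_ind
    a = _convolve_kernel(eps_a, coeffs, cfg.length)
    b = _convolve_kernel(eps_b, coeffs, cfg.length)
    sr = cfg.sampling_rate
    return TimeSeries(a, sr), TimeSeries(b, sr)
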