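"""Descriptive criticality diagnostics for space-time diagrams.

Two estimators, both deliberately plain:

* the least-squares log-log slope of the density-of-ones decay
  (power-law decay of the active-site density is the classic signature
  of an absorbing-state critical point), and
* the log-log slope of the periodogram of the decimal-expression time
  series (a slope near -1 is "1/f noise", near 0 white noise, near -2
  a random walk).

Neither performs model selection or goodness-of-fit testing; they are
exploratory summaries, not fitted models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .eca_core import SpaceTimeDiagram

__all__ = [
    "density_series",
    "decimal_series",
    "powerlaw_exponent",
    "PowerLawFit",
    "SpectralFit",
    "spectrum_slope",
]


def density_series(diagram: SpaceTimeDiagram) -> np.ndarray:
    """Fraction of state-1 cells in each diagram row (exact row means)."""
    rows = np.asarray(diagram.rows if isinstance(diagram, SpaceTimeDiagram) else diagram)
    if rows.size == 0:
        raise ValueError("empty diagram")
    return rows.mean(axis=1)


def decimal_series(diagram: SpaceTimeDiagram, raw: bool = False) -> np.ndarray:
    """Each row read as a binary fraction in [0, 1).

    Row ``(c_0, ..., c_{N-1})`` maps to ``sum_i c_i 2^-(i+1)``, which
    preserves the lexicographic ordering of configurations while staying
    width-independent. ``raw=True`` returns the plain big-endian integer
    value instead (requires N <= 62).
    """
    rows = np.asarray(diagram.rows if isinstance(diagram, SpaceTimeDiagram) else diagram)
    n = rows.shape[1]
    if raw:
        if n > 62:
            raise ValueError("raw integer expression overflows for N > 62")
        return rows.astype(np.int64) @ (1 << np.arange(n - 1, -1, -1))
    return rows @ (0.5 ** np.arange(1, n + 1))


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    stderr: float
    intercept: float
    fit_window: tuple


@dataclass(frozen=True)
class SpectralFit:
    frequencies: np.ndarray
    power: np.ndarray
    slope: float
    stderr: float
    fit_window: tuple


def powerlaw_exponent(
    series: np.ndarray, fit_window: tuple[int, int] | None = None
) -> PowerLawFit:
    """Least-squares slope of log density versus log time.

    ``fit_window = (t0, t1)`` selects times t0 <= t <= t1 (1-based, time
    0 is excluded since log 0 is undefined); the default uses every
    t >= 1. All densities in the window must be strictly positive —
    shrink the window to stop before the series hits zero.
    """
    series = np.asarray(series, dtype=float)
    t0, t1 = fit_window if fit_window is not None else (1, len(series) - 1)
    if not 1 <= t0 <= t1 < len(series):
        raise ValueError(f"fit window ({t0}, {t1}) outside series times 1..{len(series) - 1}")
    t = np.arange(t0, t1 + 1)
    rho = series[t0 : t1 + 1]
    if (rho <= 0).any():
        raise ValueError(
            "density reaches zero inside the fit window; shrink the window "
            "to the strictly positive range"
        )
    res = stats.linregress(np.log(t), np.log(rho))
    return PowerLawFit(float(res.slope), float(res.stderr), float(res.intercept), (t0, t1))


def spectrum_slope(
    series: np.ndarray, fit_window: tuple[float, float] | None = None
) -> SpectralFit:
    """Log-log slope of the periodogram of a mean-removed time series.

    ``fit_window = (f_lo, f_hi)`` restricts the fit to frequencies in
    that band (cycles per sample, zero excluded); the default fits the
    whole positive-frequency support. A slope near -1 is 1/f noise.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 64:
        raise ValueError("series too short for a spectral fit (need >= 64 samples)")
    freqs, power = signal.periodogram(series - series.mean(), detrend=False)
    keep = freqs > 0
    freqs, power = freqs[keep], power[keep]
    if fit_window is not None:
        f_lo, f_hi = fit_window
        band = (freqs >= f_lo) & (freqs <= f_hi)
        if band.sum() < 2:
            raise ValueError(
                f"fit window ({f_lo}, {f_hi}) selects fewer than 2 frequencies "
                f"in the support ({freqs[0]:.3g}, {freqs[-1]:.3g})"
            )
    else:
        f_lo, f_hi = float(freqs[0]), float(freqs[-1])
        band = np.ones_like(freqs, dtype=bool)
    pw = power[band]
    if (pw <= 0).any():
        # zero periodogram ordinates (e.g. a pure sinusoid elsewhere) carry
        # no slope information; drop them rather than fail on log(0)
        band = band & (power > 0)
        pw = power[band]
        if pw.size < 2:
            raise ValueError("periodogram has fewer than 2 positive ordinates in the window")
    res = stats.linregress(np.log(freqs[band]), np.log(pw))
    return SpectralFit(freqs, power, float(res.slope), float(res.stderr), (f_lo, f_hi))
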