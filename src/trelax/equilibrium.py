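"""Equilibrium-side characterization: spectra, thermal melts, activity.

Covers the steady-state measurements that accompany a relaxation-kinetics
study of a Trp-probed enzyme: integration of emission bands and
percent-of-apoenzyme quenching ratios, temperature series of integrated
intensities corrected for the intrinsic Trp response, sigmoidal melting
curves monitored by CD ellipticity at 222 nm, and relative catalytic
activity from initial rates of NADPH absorbance decay at 340 nm.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "SpectrumRecord",
    "MeltFitResult",
    "integrate_band",
    "integrate_full_peak",
    "percent_of_apo",
    "normalize_spectrum_max",
    "sum_spectra",
    "temperature_series",
    "fit_melt",
    "relative_activity",
]


@dataclass
class SpectrumRecord:
    """One emission spectrum: wavelength (nm, strictly increasing) vs intensity."""

    wavelength: np.ndarray
    intensity: np.ndarray
    complex_label: str = ""
    temperature: float = float("nan")

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must have equal length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")


@dataclass(frozen=True)
class MeltFitResult:
    """Sigmoid fit of a thermal melt: midpoint Tm, width, baselines, errors."""

    Tm: float
    width: float
    folded_baseline: float
    unfolded_baseline: float
    Tm_se: float
    width_se: float
    converged: bool
    rms: float


def integrate_band(s: SpectrumRecord, lo: float, hi: float) -> float:
    """Trapezoidal integral of a spectrum over [lo, hi] nm.

    Band edges that fall between grid points are handled by linear
    interpolation, so the integral equals the exact trapezoid area of the
    piecewise-linear spectrum restricted to the band (e.g. the 327-353 nm
    window of a T-jump bandpass filter).
    """
    if lo >= hi:
        raise ValueError(f"band limits must satisfy lo < hi, got [{lo}, {hi}]")
    wl = s.wavelength
    if hi < wl[0] or lo > wl[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] lies outside the recorded range [{wl[0]}, {wl[-1]}]")
    lo_c, hi_c = max(lo, wl[0]), min(hi, wl[-1])
    inner = (wl > lo_c) & (wl < hi_c)
    grid = np.concatenate(([lo_c], wl[inner], [hi_c]))
    vals = np.interp(grid, wl, s.intensity)
    return float(np.trapezoid(vals, grid))


def integrate_full_peak(s: SpectrumRecord) -> float:
    """Trapezoidal integral over the entire recorded wavelength range."""
    return float(np.trapezoid(s.intensity, s.wavelength))


def percent_of_apo(complex_integral: float, apo_integral: float) -> float:
    """Integrated intensity of a complex as a percentage of the apoenzyme's."""
    if apo_integral <= 0:
        raise ValueError(f"apo integral must be positive, got {apo_integral}")
    return 100.0 * complex_integral / apo_integral


def normalize_spectrum_max(s: SpectrumRecord) -> SpectrumRecord:
    """Scale a spectrum so its peak intensity equals 1."""
    peak = float(np.max(np.abs(s.intensity)))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return replace(s, intensity=s.intensity / peak)


def sum_spectra(spectra: Sequence[SpectrumRecord]) -> SpectrumRecord:
    """Pointwise sum of spectra; off-grid records are resampled onto the first grid."""
    if not spectra:
        raise ValueError("need at least one spectrum to sum")
    grid = spectra[0].wavelength
    total = np.zeros_like(grid)
    for s in spectra:
        if s.wavelength.shape == grid.shape and np.allclose(s.wavelength, grid):
            total = total + s.intensity
        else:
            total = total + np.interp(grid, s.wavelength, s.intensity)
    return SpectrumRecord(wavelength=grid.copy(), intensity=total,
                          complex_label="sum", temperature=spectra[0].temperature)


def temperature_series(temperatures: Sequence[float],
                       sample_intensities: Sequence[float],
                       reference_intensities: Sequence[float],
                       order: str = "normalize_then_subtract") -> np.ndarray:
    """Intrinsic-Trp-corrected change-in-intensity series.

    Both series are integrated band intensities on the *same* temperature
    grid (12-45 degC in 3 degC steps in the standard protocol).  With the
    default order, each series is normalized to 1 at the lowest temperature
    and the reference is subtracted, so the output at the lowest temperature
    is exactly 0 and positive values mean the complex brightened faster
    than free tryptophan dimmed:

        delta(T) = S(T)/S(T_min) - R(T)/R(T_min)

    ``order="subtract_then_normalize"`` instead subtracts the raw reference
    first and normalizes the corrected series to its own first value:
    delta(T) = (S - R)/(S_0 - R_0) - 1.
    """
    T = np.asarray(temperatures, dtype=float)
    S = np.asarray(sample_intensities, dtype=float)
    R = np.asarray(reference_intensities, dtype=float)
    if not (T.shape == S.shape == R.shape):
        raise ValueError("temperature, sample and reference grids must match")
    if order == "normalize_then_subtract":
        if S[0] == 0 or R[0] == 0:
            raise ValueError("first-temperature intensity must be nonzero")
        return S / S[0] - R / R[0]
    if order == "subtract_then_normalize":
        c = S - R
        if c[0] == 0:
            raise ValueError("corrected series is zero at the lowest temperature")
        return c / c[0] - 1.0
    raise ValueError(f"unknown correction order: {order!r}")


def _logistic(T, folded, unfolded, Tm, width):
    return unfolded + (folded - unfolded) / (1.0 + np.exp((T - Tm) / width))


def fit_melt(temperatures: Sequence[float],
             ellipticity: Sequence[float]) -> MeltFitResult:
    """Fit a thermal melt to a four-parameter logistic and report Tm.

    The model has folded and unfolded baselines, a midpoint Tm and a
    transition width; the loss of (negative) 222 nm ellipticity with
    temperature traces the unfolding transition.  A fit whose midpoint
    falls outside the measured range, whose transition amplitude is not
    resolved above the residual noise, or which fails to converge is
    flagged ``converged=False``.
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(ellipticity, dtype=float)
    if T.size < 6:
        raise ValueError("melt fit needs at least 6 points across the transition")
    folded0, unfolded0 = float(y[0]), float(y[-1])
    mid = 0.5 * (folded0 + unfolded0)
    idx = int(np.argmin(np.abs(y - mid)))
    p0 = [folded0, unfolded0, float(T[idx]), max(0.02 * (T[-1] - T[0]), 1.0)]
    ok = True
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _logistic, T, y, p0=p0,
                bounds=([-np.inf, -np.inf, T[0] - 50, 1e-3],
                        [np.inf, np.inf, T[-1] + 50, np.inf]),
                maxfev=20000)
    except (RuntimeError, ValueError):
        ok = False
        popt = np.array(p0)
        pcov = np.full((4, 4), np.nan)
    folded, unfolded, Tm, width = popt
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    resid = y - _logistic(T, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    if not (T[0] <= Tm <= T[-1]):
        ok = False
    if abs(folded - unfolded) < max(4.0 * rms, 1e-12 * max(abs(folded), 1.0)):
        ok = False  # no resolved transition (e.g. flat input)
    return MeltFitResult(
        Tm=float(Tm), width=float(width),
        folded_baseline=float(folded), unfolded_baseline=float(unfolded),
        Tm_se=float(se[2]), width_se=float(se[3]),
        converged=ok, rms=rms)


def _initial_rate(time: np.ndarray, a: np.ndarray,
                  window: int | None = None) -> float:
    """Initial-rate magnitude from the early linear segment of an A340 trace.

    The slope is taken by ordinary least squares over the first 10% of the
    points or the longest early segment with R^2 >= 0.99, whichever is
    shorter (minimum 3 points); returns -slope so a decaying trace gives a
    positive rate.
    """
    n = time.size
    if window is None:
        w10 = max(3, n // 10)
        w = w10
        for m in range(w10, 2, -1):
            res = linregress(time[:m], a[:m])
            if np.isclose(np.std(a[:m]), 0) or res.rvalue ** 2 >= 0.99:
                w = m
                break
        else:
            w = 3
    else:
        w = max(3, int(window))
    slope = linregress(time[:w], a[:w]).slope
    return -float(slope)


def relative_activity(sample_time: Sequence[float], sample_a340: Sequence[float],
                      wt_time: Sequence[float], wt_a340: Sequence[float],
                      window: int | None = None) -> float:
    """Initial rate of a mutant trace as a percentage of the wild-type rate.

    Rates are the early-time OLS slopes of the 340 nm absorbance decay
    (NADPH oxidation); ``window`` optionally fixes the number of leading
    points used for both traces.
    """
    st, sa = np.asarray(sample_time, float), np.asarray(sample_a340, float)
    wt, wa = np.asarray(wt_time, float), np.asarray(wt_a340, float)
    rate_wt = _initial_rate(wt, wa, window)
    rate_s = _initial_rate(st, sa, window)
    scale = max(abs(wa).max(), 1e-30) / max(wt[-1] - wt[0], 1e-30)
    if abs(rate_wt) < 1e-12 * scale:
        raise ValueError("wild-type initial rate is ~0; relative activity undefined")
    return 100.0 * rate_s / rate_wt
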