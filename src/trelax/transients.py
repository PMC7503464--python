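"""Relaxation-transient preprocessing and double-exponential fitting.

A temperature-jump transient is a fluorescence time course recorded after a
rapid (ns) heating pulse.  Processing follows the standard protocol for
Trp-probed T-jump data: subtract the intrinsic temperature response of
tryptophan using a free-Trp reference transient, normalize the trace to 100
at its initial intensity (so the signal reads as percent change), then fit
a double exponential

    F(t) = baseline + A_fast * (1 - exp(-k_fast t)) + A_slow * (1 - exp(-k_slow t))

whose two rates are the relaxation rates of the fast (binding-coupled) and
slow (conformational) phases.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TransientRecord",
    "ExpFitResult",
    "subtract_reference",
    "normalize_transient",
    "fit_double_exponential",
    "preprocess_transient",
]

#: Fraction of leading points used as the "initial intensity" window.
DEFAULT_PREJUMP_FRAC = 0.01


@dataclass
class TransientRecord:
    """One T-jump fluorescence time course with sample metadata.

    ``time`` is in seconds and strictly increasing; ``intensity`` is in
    arbitrary detector units (percent units after normalization).
    Concentrations are total concentrations in uM; temperatures in Celsius.
    """

    time: np.ndarray
    intensity: np.ndarray
    enzyme_total: float = 0.0
    ligand_total: float = 0.0
    T_initial: float = float("nan")
    T_final: float = float("nan")
    replicate: int = 0
    label: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time.size < 10:
            raise ValueError("transient needs at least 10 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def initial_intensity(self, window_frac: float = DEFAULT_PREJUMP_FRAC) -> float:
        """Mean intensity over the leading window (the pre-jump level)."""
        k = max(1, int(round(window_frac * self.time.size)))
        return float(np.mean(self.intensity[:k]))


@dataclass(frozen=True)
class ExpFitResult:
    """Rates, amplitudes and diagnostics from a double-exponential fit.

    Rates are sorted so ``k_fast >= k_slow``.  Amplitudes are in the units
    of the fitted trace (percent units for normalized transients).  Sample
    metadata from the fitted record is carried along so downstream
    concentration-dependence analysis can pair each rate with its sample.
    """

    k_fast: float
    k_slow: float
    amp_fast: float
    amp_slow: float
    baseline: float
    k_fast_se: float
    k_slow_se: float
    amp_fast_se: float
    amp_slow_se: float
    baseline_se: float
    rms: float
    converged: bool
    warnings: tuple[str, ...] = ()
    enzyme_total: float = 0.0
    ligand_total: float = 0.0
    replicate: int = 0
    label: str = ""


def _interp_reference(sample: TransientRecord, reference: TransientRecord) -> np.ndarray:
    lo = max(sample.time[0], reference.time[0])
    hi = min(sample.time[-1], reference.time[-1])
    if hi <= lo:
        raise ValueError("sample and reference time grids do not overlap")
    return np.interp(sample.time, reference.time, reference.intensity)


def subtract_reference(sample: TransientRecord, reference: TransientRecord,
                       window_frac: float = DEFAULT_PREJUMP_FRAC) -> TransientRecord:
    """Remove the intrinsic tryptophan temperature response from a transient.

    The reference (a free-tryptophan transient recorded under the same jump)
    is resampled onto the sample grid, scaled so its pre-jump intensity
    matches the sample's pre-jump intensity, and subtracted:

        corrected = sample - s * reference,   s = I0_sample / I0_reference

    The applied scale factor is recorded in ``extras["reference_scale"]``.
    A reference that is identically zero leaves the sample unchanged.
    """
    ref = _interp_reference(sample, reference)
    if not np.any(ref):
        out = replace(sample, intensity=sample.intensity.copy())
        out.extras = {**sample.extras, "reference_scale": 0.0}
        return out
    k = max(1, int(round(window_frac * sample.time.size)))
    ref_pre = float(np.mean(ref[:k]))
    if ref_pre == 0.0:
        raise ValueError("reference pre-jump intensity is zero; cannot scale")
    s = sample.initial_intensity(window_frac) / ref_pre
    out = replace(sample, intensity=sample.intensity - s * ref)
    out.extras = {**sample.extras, "reference_scale": s}
    return out


def normalize_transient(t: TransientRecord,
                        window_frac: float = DEFAULT_PREJUMP_FRAC) -> TransientRecord:
    """Scale a transient so its initial (pre-jump window) intensity is 100.

    After normalization the trace reads directly as percent of the initial
    fluorescence.  The window used and the divisor are recorded in
    ``extras``.
    """
    i0 = t.initial_intensity(window_frac)
    if i0 <= 0:
        raise ValueError(f"initial intensity must be positive, got {i0}")
    out = replace(t, intensity=100.0 * t.intensity / i0)
    out.extras = {**t.extras, "normalization_divisor": i0,
                  "normalization_window_frac": window_frac}
    return out


def preprocess_transient(sample: TransientRecord,
                         reference: TransientRecord | None = None,
                         window_frac: float = DEFAULT_PREJUMP_FRAC) -> TransientRecord:
    """Reference-subtract (optional) and normalize to the percent-change scale.

    Without a reference this is plain normalization (initial = 100).  With a
    reference, the subtraction removes the intrinsic component *including*
    the shared baseline, leaving a pure kinetic-change trace near zero; that
    trace is then expressed as percent of the sample's own pre-jump
    intensity, offset to start at 100, so both paths land on the same
    "percent change, initial = 100" scale the fitter expects.
    """
    if reference is None:
        return normalize_transient(sample, window_frac)
    i0 = sample.initial_intensity(window_frac)
    if i0 <= 0:
        raise ValueError(f"initial intensity must be positive, got {i0}")
    corrected = subtract_reference(sample, reference, window_frac)
    out = replace(corrected, intensity=100.0 * corrected.intensity / i0 + 100.0)
    out.extras = {**corrected.extras, "normalization_divisor": i0,
                  "normalization_window_frac": window_frac}
    return out


def _double_exp(t: np.ndarray, baseline: float, a_fast: float, k_fast: float,
                a_slow: float, k_slow: float) -> np.ndarray:
    return (baseline
            + a_fast * -np.expm1(-k_fast * t)
            + a_slow * -np.expm1(-k_slow * t))


def _peel_guesses(time: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Initial guesses by log-time peeling.

    Fit the slow tail first: on the late third of the trace the residual to
    the final plateau is dominated by the slow phase, so a log-linear fit of
    |plateau - F| against t yields k_slow and its amplitude.  Subtracting
    that component and repeating on the early points yields the fast phase.
    Falls back to span-based heuristics when the trace is too degenerate to
    peel (e.g. flat or non-monotone noise).
    """
    n = time.size
    baseline = float(np.mean(y[: max(1, n // 100)]))
    plateau = float(np.mean(y[-max(2, n // 20):]))
    total = plateau - baseline
    t_span = time[-1] - time[0]
    k_slow_fb = 3.0 / t_span          # a phase resolvable within the window
    k_fast_fb = 10.0 * k_slow_fb

    def _loglin(t_seg: np.ndarray, d_seg: np.ndarray) -> tuple[float, float] | None:
        good = d_seg > 0
        if good.sum() < 5:
            return None
        coef = np.polyfit(t_seg[good], np.log(d_seg[good]), 1)
        k = -coef[0]
        amp = float(np.exp(coef[1]))
        if not np.isfinite(k) or k <= 0:
            return None
        return k, amp

    sign = 1.0 if total >= 0 else -1.0
    resid = sign * (plateau - y)      # a_f e^-kf t + a_s e^-ks t, positive if clean
    late = slice(2 * n // 3, n)
    slow = _loglin(time[late], resid[late])
    if slow is None:
        return baseline, total / 2 or 1.0, k_fast_fb, total / 2 or 1.0, k_slow_fb
    k_s, a_s = slow
    resid_fast = resid - a_s * np.exp(-k_s * time)
    early = slice(0, n // 3)
    fast = _loglin(time[early], resid_fast[early])
    if fast is None or fast[0] <= k_s:
        k_f, a_f = 10.0 * k_s, max(abs(total) - a_s, 0.1 * a_s)
    else:
        k_f, a_f = fast
    return baseline, sign * a_f, k_f, sign * a_s, k_s


def fit_double_exponential(t: TransientRecord,
                           guesses: Sequence[float] | None = None,
                           fit_baseline: bool = True) -> ExpFitResult:
    """Least-squares double-exponential fit of one relaxation transient.

    Parameters
    ----------
    t : TransientRecord
        The (preprocessed) transient.  Should span at least ~3/k_slow so the
        slow phase is resolved; a shorter window triggers a warning.
    guesses : (k_fast, k_slow), optional
        Rate starting values.  When omitted, starting values come from
        log-time peeling of the trace itself.
    fit_baseline : bool
        Float the baseline offset (default) or pin it to the initial level.

    Returns
    -------
    ExpFitResult with rates sorted descending, standard errors from the
    covariance of the fit, the residual RMS, a convergence flag and any
    identifiability warnings (flat trace, rate collapse k_fast/k_slow < 1.5,
    window too short).
    """
    time, y = t.time, t.intensity
    warn: list[str] = []
    b0, a_f0, k_f0, a_s0, k_s0 = _peel_guesses(time, y)
    if guesses is not None:
        k_f0, k_s0 = float(max(guesses)), float(min(guesses))
    t_span = time[-1] - time[0]
    p0 = [b0, a_f0, k_f0, a_s0, k_s0]
    kmin = 0.01 / t_span
    lower = [-np.inf, -np.inf, kmin, -np.inf, kmin]
    upper = [np.inf, np.inf, np.inf, np.inf, np.inf]
    p0[2] = max(p0[2], 2 * kmin)
    p0[4] = max(p0[4], 2 * kmin)

    converged = True
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            popt, pcov = curve_fit(_double_exp, time, y, p0=p0,
                                   bounds=(lower, upper), maxfev=20000)
    except (RuntimeError, ValueError):
        converged = False
        popt = np.array(p0)
        pcov = np.full((5, 5), np.nan)

    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(5, np.nan)
    baseline, a_f, k_f, a_s, k_s = popt
    b_se, a_f_se, k_f_se, a_s_se, k_s_se = se
    if k_f < k_s:  # enforce rate ordering: fast phase reported first
        a_f, a_s = a_s, a_f
        k_f, k_s = k_s, k_f
        a_f_se, a_s_se = a_s_se, a_f_se
        k_f_se, k_s_se = k_s_se, k_f_se

    resid = y - _double_exp(time, baseline, a_f, k_f, a_s, k_s)
    rms = float(np.sqrt(np.mean(resid ** 2)))

    if t_span * k_s < 3.0:
        warn.append("time window shorter than 3/k_slow; slow rate may be ill-determined")
        _warnings.warn(warn[-1], stacklevel=2)
    if abs(a_f) + abs(a_s) < 1e-6 * max(abs(baseline), 1.0) or np.ptp(y) == 0:
        warn.append("amplitudes are ~0; rates are not identifiable")
    elif k_s > 0 and k_f / k_s < 1.5:
        warn.append("rate collapse: k_fast/k_slow < 1.5, phases not separable")

    return ExpFitResult(
        k_fast=float(k_f), k_slow=float(k_s),
        amp_fast=float(a_f), amp_slow=float(a_s), baseline=float(baseline),
        k_fast_se=float(k_f_se), k_slow_se=float(k_s_se),
        amp_fast_se=float(a_f_se), amp_slow_se=float(a_s_se),
        baseline_se=float(b_se),
        rms=rms, converged=converged, warnings=tuple(warn),
        enzyme_total=t.enzyme_total, ligand_total=t.ligand_total,
        replicate=t.replicate, label=t.label,
    )
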