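"""Concentration-dependence analysis of relaxation rates.

For a single bimolecular binding step E + L <=> EL, the relaxation rate
after a small perturbation is linear in the sum of the free concentrations:

    k_obs = k_on * ([E]_free + [L]_free) + k_off

so a relaxation phase that tracks concentration reports on binding, while a
concentration-independent phase reports on a unimolecular (conformational)
event.  This module classifies each phase by the significance of its
Pearson correlation with the free-concentration sum, extracts k_on and
k_off from the linear fit of the fast rate, forms Kd = k_off/k_on, and
pools the slow rates across all samples and replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .binding import BindingParameters, adjust_kd, free_concentrations
from .transients import ExpFitResult

__all__ = [
    "CorrelationTest",
    "KineticsSummary",
    "pearson_r",
    "critical_r",
    "classify_dependence",
    "fit_rate_vs_concentration",
    "kd_from_rates",
    "pool_slow_rates",
    "summarize_enzyme",
]

DEFAULT_CONFIDENCE_LEVELS = (0.99, 0.90, 0.80)


@dataclass(frozen=True)
class CorrelationTest:
    """A Pearson correlation with its significance thresholds and verdict.

    ``verdict`` is ``"dependent"`` when r clears the highest-confidence
    critical value, ``"weakly_dependent"`` when it clears only the middle
    one, ``"independent"`` otherwise.  Negative correlations with
    concentration are physically meaningless for a binding step and are
    always classified independent.
    """

    r: float
    n: int
    df: int
    confidence_levels: tuple[float, ...]
    critical_values: tuple[float, ...]
    verdict: str


@dataclass(frozen=True)
class KineticsSummary:
    """Per-enzyme outcome of the relaxation analysis.

    ``k_on`` (uM^-1 s^-1) and ``k_off`` (s^-1) are the slope and intercept
    of the fast rate against the free-concentration sum; they are withheld
    (NaN) when the fast phase shows no significant concentration
    dependence.  ``kd_tjump`` = k_off/k_on is compared with the
    calorimetric ``kd_itc`` through ``kd_ratio``.
    """

    label: str
    k_on: float
    k_on_se: float
    k_off: float
    k_off_se: float
    kd_tjump: float
    kd_itc: float
    kd_ratio: float
    fast_test: CorrelationTest
    slow_test: CorrelationTest
    slow_mean: float
    slow_sd: float
    slow_n: int
    sum_free: tuple[float, ...]
    k_fast: tuple[float, ...]
    k_slow: tuple[float, ...]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient of two equal-length samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def critical_r(confidence: float, df: int) -> float:
    """Two-tailed critical value of Pearson's r at a confidence level.

    Under the null of no correlation, t = r sqrt(df) / sqrt(1 - r^2)
    follows Student's t with df = n - 2 degrees of freedom; inverting at
    the two-tailed quantile t_c gives

        r_crit = t_c / sqrt(t_c^2 + df)

    e.g. 0.505 at 99% confidence with df = 23.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    t_c = stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, df)
    return float(t_c / math.sqrt(t_c * t_c + df))


def classify_dependence(r: float, n: int,
                        levels: Sequence[float] = DEFAULT_CONFIDENCE_LEVELS
                        ) -> CorrelationTest:
    """Classify a rate-vs-concentration correlation as dependent or not.

    ``levels`` are confidence levels in decreasing order (default
    99%/90%/80%).  r at or above the 99% critical value -> ``dependent``;
    between the 90% and 99% values -> ``weakly_dependent``; anything else,
    including every negative r, -> ``independent``.
    """
    levels = tuple(sorted(levels, reverse=True))
    df = n - 2
    crits = tuple(critical_r(c, df) for c in levels)
    if r < -1.0 or r > 1.0:
        raise ValueError(f"r must lie in [-1, 1], got {r}")
    if r < 0:
        verdict = "independent"
    elif r >= crits[0]:
        verdict = "dependent"
    elif len(crits) > 1 and r >= crits[1]:
        verdict = "weakly_dependent"
    else:
        verdict = "independent"
    return CorrelationTest(r=float(r), n=int(n), df=df,
                           confidence_levels=levels, critical_values=crits,
                           verdict=verdict)


def fit_rate_vs_concentration(sum_free: Sequence[float],
                              k_obs: Sequence[float]
                              ) -> tuple[float, float, float, float]:
    """OLS line through observed rates vs the free-concentration sum.

    Returns ``(slope, intercept, slope_se, intercept_se)``; for the fast
    relaxation phase of a two-state binding step the slope is k_on
    (uM^-1 s^-1) and the intercept is k_off (s^-1).
    """
    x = np.asarray(sum_free, float)
    y = np.asarray(k_obs, float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentration values")
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.stderr), float(res.intercept_stderr))


def kd_from_rates(k_on: float, k_off: float) -> float:
    """Dissociation constant (uM) from the kinetic rate constants: k_off/k_on."""
    if k_on <= 0:
        raise ValueError(f"k_on must be positive, got {k_on}")
    return k_off / k_on


def pool_slow_rates(slow_rates: Sequence[float]) -> tuple[float, float, int]:
    """Mean, sample standard deviation and count of the pooled slow rates.

    The slow phase is concentration independent, so rates from every
    ligand concentration and replicate are pooled into one average (the
    5 x 5 design gives n = 25 and df = 23 for the companion correlation).
    """
    rates = np.asarray(slow_rates, float)
    if rates.size < 2:
        raise ValueError("pooling needs at least 2 rates")
    return float(np.mean(rates)), float(np.std(rates, ddof=1)), int(rates.size)


def summarize_enzyme(fits: Iterable[ExpFitResult],
                     params: BindingParameters,
                     kd_itc: float,
                     T_final_C: float = 36.0,
                     levels: Sequence[float] = DEFAULT_CONFIDENCE_LEVELS,
                     label: str = "") -> KineticsSummary:
    """Full concentration-dependence analysis for one enzyme.

    For every converged per-transient fit, the free-concentration sum at
    the post-jump temperature is computed from the calorimetric binding
    parameters (van 't Hoff-adjusted Kd), both phases are tested for
    concentration dependence, the fast phase is regressed to give k_on and
    k_off (withheld if the fast phase is classified independent), and the
    slow rates are pooled.
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to summarize")
    kd_T = adjust_kd(params, T_final_C + 273.15)
    x = np.array([
        free_concentrations(f.enzyme_total, f.ligand_total, kd_T).sum_free
        for f in fits])
    if np.unique(np.round(x, 9)).size < 3:
        raise ValueError("need fits at >= 3 distinct concentration levels")
    y_fast = np.array([f.k_fast for f in fits])
    y_slow = np.array([f.k_slow for f in fits])
    n = len(fits)

    fast_test = classify_dependence(pearson_r(x, y_fast), n, levels)
    slow_test = classify_dependence(pearson_r(x, y_slow), n, levels)

    if fast_test.verdict == "independent":
        # no significant concentration dependence: a binding interpretation
        # of the fast phase is unsupported, so rate constants are withheld
        k_on = k_off = k_on_se = k_off_se = kd_tj = ratio = float("nan")
    else:
        k_on, k_off, k_on_se, k_off_se = fit_rate_vs_concentration(x, y_fast)
        kd_tj = kd_from_rates(k_on, k_off)
        ratio = kd_tj / kd_itc if kd_itc > 0 else float("nan")

    slow_mean, slow_sd, slow_n = pool_slow_rates(y_slow)
    return KineticsSummary(
        label=label or (fits[0].label.split("/")[0] if fits[0].label else ""),
        k_on=k_on, k_on_se=k_on_se, k_off=k_off, k_off_se=k_off_se,
        kd_tjump=kd_tj, kd_itc=float(kd_itc), kd_ratio=ratio,
        fast_test=fast_test, slow_test=slow_test,
        slow_mean=slow_mean, slow_sd=slow_sd, slow_n=slow_n,
        sum_free=tuple(x), k_fast=tuple(y_fast), k_slow=tuple(y_slow),
    )
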