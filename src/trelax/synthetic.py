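"""Synthetic data generation for the full analysis pipeline.

Emulates the inputs of a Trp-fluorescence T-jump study of an enzyme-ligand
system: relaxation transients with a fast binding-coupled phase and a slow
conformational phase, a free-tryptophan reference transient, emission
spectra with per-complex quenching, CD thermal-melt curves, and initial-rate
activity traces.  Every generator is seeded and deterministic, and records
its ground-truth parameters so recovery by the analysis stages can be
tested quantitatively.

The default kinetic scenario mirrors a typical binary folate-complex
titration: five ligand concentrations up to 200 uM at 100 uM enzyme, five
replicates each, a 29 -> 36 degC jump, k_on = 31 uM^-1 s^-1,
k_off = 1100 s^-1, a 400 s^-1 slow phase, and 1% Gaussian noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import BindingParameters, adjust_kd, free_concentrations
from .equilibrium import SpectrumRecord
from .transients import TransientRecord

__all__ = [
    "KineticScenario",
    "EmissionBand",
    "SpectralScenario",
    "generate_transient",
    "generate_reference_transient",
    "generate_spectrum",
    "generate_melt_curve",
    "generate_activity_trace",
    "default_spectral_scenario",
    "true_fast_rate",
]

#: Minimum allowed separation between the slow rate and any realized fast
#: rate, so a double-exponential fit can resolve the two phases.
MIN_RATE_SEPARATION = 2.0


def _default_binding() -> BindingParameters:
    # Kd 4.7 uM at the 29 degC pre-jump temperature (calorimetric value for
    # the wild-type folate complex); the enthalpy is a placeholder typical
    # of exothermic folate binding, not a measured value.
    return BindingParameters(kd_ref=4.7, delta_H=-10.0, T_ref=302.15)


@dataclass
class KineticScenario:
    """Ground-truth model for one simulated T-jump titration.

    Rates: ``k_on`` (uM^-1 s^-1), ``k_off`` and ``k_slow`` (s^-1).
    ``amp_fast``/``amp_slow`` are signed fractional fluorescence amplitudes
    (0.10 = a 10% rise; ligand dissociation relieves roughly half of the
    Trp quenching at equilibrium, so post-jump changes of this order are
    typical).  ``noise_sd`` is the Gaussian noise level as a
    fraction of the pre-jump intensity ``f0``.  ``background_frac`` mixes a
    scaled copy of the intrinsic-Trp step into each sample transient (0 by
    default, giving the pure kinetic closed form).  ``binding`` supplies the
    calorimetric Kd and enthalpy used to compute free concentrations at the
    post-jump temperature.
    """

    k_on: float = 31.0
    k_off: float = 1100.0
    k_slow: float = 400.0
    amp_fast: float = 0.10
    amp_slow: float = 0.08
    enzyme_total: float = 100.0
    ligand_totals: tuple[float, ...] = (25.0, 50.0, 100.0, 150.0, 200.0)
    replicates: int = 5
    t_start: float = 1e-6
    t_end: float = 1e-2
    n_points: int = 1000
    noise_sd: float = 0.01
    T_initial: float = 29.0
    T_final: float = 36.0
    f0: float = 1000.0
    trp_step_frac: float = 0.08
    background_frac: float = 0.0
    binding: BindingParameters = field(default_factory=_default_binding)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off < 0 or self.k_slow <= 0:
            raise ValueError("rates must satisfy k_on > 0, k_off >= 0, k_slow > 0")
        self.ligand_totals = tuple(float(c) for c in self.ligand_totals)
        if any(c < 0 for c in self.ligand_totals):
            raise ValueError("ligand concentrations must be non-negative")
        if len(set(self.ligand_totals)) < 3:
            raise ValueError("need at least 3 distinct ligand concentrations")
        if not (0 < self.t_start < self.t_end):
            raise ValueError("time grid must satisfy 0 < t_start < t_end")
        if self.n_points < 10:
            raise ValueError("need at least 10 time points")
        if self.f0 <= 0:
            raise ValueError(f"pre-jump intensity f0 must be positive, got {self.f0}")
        for c in self.ligand_totals:
            kf = true_fast_rate(self, c)
            ratio = kf / self.k_slow
            if 1.0 / MIN_RATE_SEPARATION < ratio < MIN_RATE_SEPARATION:
                raise ValueError(
                    f"k_slow={self.k_slow} s^-1 is within {MIN_RATE_SEPARATION}x of the "
                    f"fast rate {kf:.1f} s^-1 at {c} uM ligand; phases unresolvable")

    @property
    def time_grid(self) -> np.ndarray:
        """Logarithmic post-jump time grid (s), bracketing both phases."""
        return np.logspace(np.log10(self.t_start), np.log10(self.t_end),
                           self.n_points)

    def kd_at_T_final(self) -> float:
        return adjust_kd(self.binding, self.T_final + 273.15)


def true_fast_rate(scenario: KineticScenario, ligand_total: float) -> float:
    """Ground-truth fast relaxation rate k_on*(E_free + L_free) + k_off (s^-1).

    Free concentrations are evaluated at the post-jump temperature with the
    van 't Hoff-adjusted Kd.
    """
    if ligand_total < 0:
        raise ValueError("ligand_total must be non-negative")
    eq = free_concentrations(scenario.enzyme_total, ligand_total,
                             scenario.kd_at_T_final())
    return scenario.k_on * eq.sum_free + scenario.k_off


def generate_transient(scenario: KineticScenario, ligand_total: float,
                       replicate_seed: int, replicate: int = 0,
                       label: str = "") -> TransientRecord:
    """Simulate one post-jump fluorescence transient.

        F(t) = F0 * [1 + A_fast (1 - e^{-k_fast t}) + A_slow (1 - e^{-k_slow t})] + eps

    with k_fast from :func:`true_fast_rate` and eps ~ N(0, (noise_sd*F0)^2)
    i.i.d. per point.  With ``background_frac > 0`` a scaled intrinsic-Trp
    step (post-jump drop of ``trp_step_frac``) is mixed in, for exercising
    reference subtraction.  Ground truth is recorded in ``extras``.
    """
    if ligand_total < 0:
        raise ValueError("ligand_total must be non-negative")
    t = scenario.time_grid
    k_fast = true_fast_rate(scenario, ligand_total)
    f0 = scenario.f0
    signal = f0 * (1.0
                   + scenario.amp_fast * -np.expm1(-k_fast * t)
                   + scenario.amp_slow * -np.expm1(-scenario.k_slow * t))
    if scenario.background_frac:
        # the intrinsic component has already completed its step on this
        # post-jump grid: a constant depressed level
        signal = signal + scenario.background_frac * f0 * (1.0 - scenario.trp_step_frac)
    rng = np.random.default_rng(replicate_seed)
    noise = rng.normal(0.0, scenario.noise_sd * f0, size=t.size) if scenario.noise_sd else 0.0
    eq = free_concentrations(scenario.enzyme_total, ligand_total,
                             scenario.kd_at_T_final())
    return TransientRecord(
        time=t, intensity=signal + noise,
        enzyme_total=scenario.enzyme_total, ligand_total=ligand_total,
        T_initial=scenario.T_initial, T_final=scenario.T_final,
        replicate=replicate, label=label,
        extras={
            "k_fast_true": k_fast,
            "k_slow_true": scenario.k_slow,
            "amp_fast_true": scenario.amp_fast,
            "amp_slow_true": scenario.amp_slow,
            "sum_free_uM": eq.sum_free,
            "kd_at_T_final_uM": scenario.kd_at_T_final(),
            "replicate_seed": int(replicate_seed),
        },
    )


def generate_reference_transient(scenario: KineticScenario,
                                 seed: int | None = None,
                                 n_prejump: int = 20,
                                 label: str = "free-Trp reference") -> TransientRecord:
    """Simulate the free-tryptophan reference transient.

    Free Trp has no binding kinetics; its fluorescence simply steps down by
    ``trp_step_frac`` when the temperature jumps (Trp emission decreases
    with temperature), instantaneously on the kinetic time scale.  The
    record includes a short pre-jump segment (t < 0) at the unheated level
    so the step is visible and the pre-jump intensity is defined.
    """
    t_post = scenario.time_grid
    t_pre = -np.logspace(np.log10(scenario.t_end * 0.1),
                         np.log10(scenario.t_start), n_prejump)
    t = np.concatenate([t_pre, t_post])
    f0 = scenario.f0
    signal = np.where(t < 0, f0, f0 * (1.0 - scenario.trp_step_frac))
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    noise = rng.normal(0.0, scenario.noise_sd * f0, size=t.size) if scenario.noise_sd else 0.0
    return TransientRecord(
        time=t, intensity=signal + noise,
        enzyme_total=0.0, ligand_total=0.0,
        T_initial=scenario.T_initial, T_final=scenario.T_final,
        replicate=0, label=label,
        extras={"trp_step_frac": scenario.trp_step_frac},
    )


@dataclass(frozen=True)
class EmissionBand:
    """Gaussian emission band: center and width in nm, peak amplitude in a.u."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.width <= 0:
            raise ValueError("band amplitude and width must be positive")


@dataclass
class SpectralScenario:
    """Emission bands per enzyme plus per-complex quench factors.

    ``quench_factors`` maps a full label ``"<enzyme>/<complex>"`` to the
    multiplier applied to the apoenzyme band (1.0 = unquenched; values
    slightly above 1 model the small brightening some complexes show).
    """

    bands: Mapping[str, EmissionBand]
    quench_factors: Mapping[str, float] = field(default_factory=dict)
    wavelength_start: float = 300.0
    wavelength_end: float = 420.0
    wavelength_step: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, q in self.quench_factors.items():
            if not 0.0 < q <= 1.2:
                raise ValueError(f"quench factor for {key!r} must be in (0, 1.2], got {q}")
        if self.wavelength_step <= 0 or self.wavelength_end <= self.wavelength_start:
            raise ValueError("wavelength grid must be increasing")

    @property
    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_end - self.wavelength_start)
                      / self.wavelength_step)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)


def default_spectral_scenario(noise_sd: float = 0.0, seed: int = 0) -> SpectralScenario:
    """Five single-Trp probe variants with field-typical bands and quenching.

    Peak amplitudes are ordered W74 > W30 > W47 > W133 > W22; W47 and W133
    are blue-shifted relative to the others.  Quench factors reproduce the
    integrated percent-of-apo pattern of the folate / NADP+ / ternary
    complexes for each variant.
    """
    bands = {
        "midW74": EmissionBand(341.0, 12.0, 100.0),
        "midW30": EmissionBand(340.0, 12.0, 85.0),
        "midW47": EmissionBand(332.0, 11.0, 60.0),
        "midW133": EmissionBand(334.0, 11.0, 45.0),
        "midW22": EmissionBand(340.0, 12.0, 30.0),
    }
    quench = {
        "midW22/nadp": 1.02, "midW22/folate": 0.52, "midW22/nadp_folate": 0.49,
        "midW30/nadp": 1.06, "midW30/folate": 0.42, "midW30/nadp_folate": 0.40,
        "midW47/nadp": 0.92, "midW47/folate": 0.71, "midW47/nadp_folate": 0.54,
        "midW74/nadp": 0.98, "midW74/folate": 0.64, "midW74/nadp_folate": 0.61,
        "midW133/nadp": 0.93, "midW133/folate": 0.64, "midW133/nadp_folate": 0.63,
    }
    return SpectralScenario(bands=bands, quench_factors=quench,
                            noise_sd=noise_sd, seed=seed)


def generate_spectrum(scenario: SpectralScenario, label: str,
                      temperature: float = 25.0) -> SpectrumRecord:
    """Simulate one emission spectrum.

    ``label`` is either an enzyme name (apoenzyme) or ``"<enzyme>/<complex>"``;
    the complex spectrum is the apo band scaled by its quench factor, plus
    Gaussian noise of ``noise_sd`` times the apo peak amplitude.
    """
    enzyme = label.split("/")[0]
    if enzyme not in scenario.bands:
        raise KeyError(f"unknown enzyme label: {enzyme!r}")
    band = scenario.bands[enzyme]
    q = 1.0
    if "/" in label:
        if label not in scenario.quench_factors:
            raise KeyError(f"no quench factor configured for {label!r}")
        q = scenario.quench_factors[label]
    wl = scenario.wavelength_grid
    signal = q * band.amplitude * np.exp(-0.5 * ((wl - band.center) / band.width) ** 2)
    rng = np.random.default_rng(scenario.seed + (zlib.crc32(label.encode()) % 100003))
    noise = rng.normal(0.0, scenario.noise_sd * band.amplitude, wl.size) \
        if scenario.noise_sd else 0.0
    return SpectrumRecord(wavelength=wl, intensity=signal + noise,
                          complex_label=label, temperature=temperature)


def generate_melt_curve(Tm: float = 48.0, width: float = 2.5,
                        baselines: tuple[float, float] = (-20.0, -2.0),
                        noise_sd: float = 0.0, seed: int = 0,
                        temperatures: Sequence[float] | None = None) -> pd.DataFrame:
    """Simulate a CD thermal melt (222 nm ellipticity vs temperature).

    Sigmoid with midpoint ``Tm`` and transition ``width`` between the
    folded and unfolded baselines; default grid is 10-90 degC in 5 degC
    steps.  Noise is Gaussian with sd ``noise_sd`` times the transition
    amplitude.  Returns a DataFrame with ``temperature_C`` and
    ``ellipticity`` columns.
    """
    if width <= 0:
        raise ValueError(f"transition width must be positive, got {width}")
    T = np.arange(10.0, 90.0 + 1e-9, 5.0) if temperatures is None \
        else np.asarray(temperatures, float)
    folded, unfolded = baselines
    y = unfolded + (folded - unfolded) / (1.0 + np.exp((T - Tm) / width))
    if noise_sd:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd * abs(folded - unfolded), T.size)
    return pd.DataFrame({"temperature_C": T, "ellipticity": y})


def generate_activity_trace(initial_rate: float, duration: float = 120.0,
                            noise_sd: float = 0.0, seed: int = 0,
                            a_start: float = 1.0, a_end: float = 0.1,
                            n_points: int = 240) -> pd.DataFrame:
    """Simulate an NADPH-oxidation absorbance trace at 340 nm.

    Exponential decay from ``a_start`` toward ``a_end`` whose slope at
    t = 0 equals ``-initial_rate`` (delta-A340 per second); a zero rate
    gives a flat trace.  Returns a DataFrame with ``time_s`` and ``A340``.
    """
    if initial_rate < 0:
        raise ValueError(f"initial_rate must be non-negative, got {initial_rate}")
    t = np.linspace(0.0, duration, n_points)
    if initial_rate == 0:
        a = np.full_like(t, a_start)
    else:
        k = initial_rate / (a_start - a_end)
        a = a_end + (a_start - a_end) * np.exp(-k * t)
    if noise_sd:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd * a_start, t.size)
    return pd.DataFrame({"time_s": t, "A340": a})
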