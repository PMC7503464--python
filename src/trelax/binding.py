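"""Two-state binding equilibrium: E + L <=> EL.

Computes the dissociation constant at the post-jump temperature via the
integrated van 't Hoff relation and the free-species concentrations from
the mass-action quadratic.  The quantity the relaxation analysis needs is
``sum_free = [E]_free + [L]_free`` at the final temperature, because for a
single bimolecular binding step the relaxation rate is

    k_obs = k_on * ([E]_free + [L]_free) + k_off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT_KCAL",
    "BindingParameters",
    "EquilibriumState",
    "adjust_kd",
    "free_concentrations",
]

#: Gas constant in kcal mol^-1 K^-1 (enthalpies are in kcal/mol, ITC convention).
GAS_CONSTANT_KCAL = 1.98720425e-3


@dataclass(frozen=True)
class BindingParameters:
    """Equilibrium thermodynamics of one enzyme-ligand pair.

    Parameters
    ----------
    kd_ref : float
        Dissociation constant in uM at the reference temperature ``T_ref``.
    delta_H : float
        Association (binding) enthalpy in kcal/mol, ITC sign convention:
        negative = exothermic binding.
    T_ref : float
        Reference temperature in K at which ``kd_ref`` was measured.
    delta_Cp : float, optional
        Heat-capacity change of association in kcal/(mol K).  Zero by
        default (constant-enthalpy van 't Hoff); provided as a hook for
        data where the curvature matters.
    """

    kd_ref: float
    delta_H: float
    T_ref: float
    delta_Cp: float = 0.0

    def __post_init__(self) -> None:
        if self.kd_ref <= 0:
            raise ValueError(f"kd_ref must be positive, got {self.kd_ref}")
        if self.T_ref <= 0:
            raise ValueError(f"T_ref must be positive (kelvin), got {self.T_ref}")


@dataclass(frozen=True)
class EquilibriumState:
    """Free and bound species concentrations (uM) at one temperature."""

    E_free: float
    L_free: float
    EL: float
    sum_free: float
    temperature: float


def adjust_kd(params: BindingParameters, T_target: float) -> float:
    """Dissociation constant (uM) at ``T_target`` (K) by integrated van 't Hoff.

    With the association constant Ka = 1/Kd and constant association
    enthalpy dH:

        ln Ka(T2) - ln Ka(T1) = -(dH/R) * (1/T2 - 1/T1)

    For exothermic binding (dH < 0) Ka falls with temperature, i.e. Kd
    rises: the complex dissociates when heated, which is the signal a
    temperature jump probes.  A nonzero ``delta_Cp`` adds the standard
    curvature terms with dH and dS referenced at ``T_ref``.
    """
    if T_target <= 0:
        raise ValueError(f"T_target must be positive (kelvin), got {T_target}")
    R = GAS_CONSTANT_KCAL
    T1, T2 = params.T_ref, float(T_target)
    dln_ka = -(params.delta_H / R) * (1.0 / T2 - 1.0 / T1)
    if params.delta_Cp != 0.0:
        # dH(T) = dH(T1) + dCp*(T - T1); integrate d(lnKa)/dT = dH(T)/(R T^2)
        dln_ka += (params.delta_Cp / R) * (
            math.log(T2 / T1) + T1 / T2 - 1.0
        )
    # ln Kd(T2) = ln Kd(T1) - dln_ka
    return params.kd_ref * math.exp(-dln_ka)


def free_concentrations(E_total: float, L_total: float, Kd: float,
                        temperature: float = float("nan")) -> EquilibriumState:
    """Solve the two-state binding equilibrium for free concentrations.

    Mass action gives the complex concentration as the physical root of

        EL^2 - (E_t + L_t + Kd) EL + E_t L_t = 0

    All concentrations in uM.  The smaller root is computed through the
    product form ``EL = 2 E_t L_t / (b + sqrt(b^2 - 4 E_t L_t))`` to avoid
    catastrophic cancellation when Kd is much smaller than the totals.
    """
    if E_total < 0 or L_total < 0:
        raise ValueError("total concentrations must be non-negative")
    if Kd <= 0:
        raise ValueError(f"Kd must be positive, got {Kd}")
    b = E_total + L_total + Kd
    disc = b * b - 4.0 * E_total * L_total
    # disc >= Kd^2 > 0 analytically; clip tiny negative round-off anyway
    root = math.sqrt(max(disc, 0.0))
    prod = E_total * L_total
    EL = 0.0 if prod == 0.0 else 2.0 * prod / (b + root)
    E_free = max(E_total - EL, 0.0)
    L_free = max(L_total - EL, 0.0)
    return EquilibriumState(
        E_free=E_free,
        L_free=L_free,
        EL=EL,
        sum_free=E_free + L_free,
        temperature=temperature,
    )
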