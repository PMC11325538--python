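"""Analytic release of the TR restraints to the 1 M standard state.

The free energy of releasing the six Boresch restraints from the bound
reference geometry into unrestrained bulk at standard concentration is

    ΔG_TR,rel = -RT ln( 8π² V0 / Z_TR ),

with V0 = 1660.5392 Å³ the per-molecule volume at 1 M, 8π² the orientational
volume, and

    Z_TR = ∫ r² sinθ sinΘ exp(-u/RT) dr dθ dΘ dφ dΦ dΨ

the configurational integral of the restraint potential u over the six
restrained coordinates with their Jacobian. Because u is a sum of
independent harmonic terms and the Jacobian factorises, Z_TR is evaluated
as a product of adaptive one-dimensional quadratures. A stiff-spring closed
form,

    Z_TR ≈ r0² sinθ0 sinΘ0 (2πRT)³ (k_r k_θ k_Θ k_φ k_Φ k_Ψ)^(-1/2),

is provided both as a fast approximation and as the analytic oracle in the
stiff limit. Releasing tight restraints into 1 M bulk yields ΔG < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .constants import ORIENTATIONAL_VOLUME, T_DEFAULT, V0_STANDARD, rt
from .restraints import TRRestraint


class DivergentIntegralError(ValueError):
    """A zero force constant makes the TR configurational integral diverge."""


@dataclass(frozen=True)
class StandardState:
    """Standard-state reference: 1 M concentration, 8π² rad³ of orientation."""

    C0: float = 1.0                      # mol/L
    V0: float = V0_STANDARD              # Å³ per molecule
    orientational_volume: float = ORIENTATIONAL_VOLUME  # rad³

    def __post_init__(self):
        expected = V0_STANDARD / self.C0
        if abs(self.V0 - expected) > 0.5:
            raise ValueError(f"V0 must equal 1/(C0·N_A) in Å³ (≈{expected:.1f})")


def _check_force_constants(tr: TRRestraint) -> None:
    names = ("k_r", "k_theta", "k_Theta", "k_phi", "k_Phi", "k_Psi")
    bad = [n for n, k in zip(names, tr.force_constants) if k <= 0]
    if bad:
        raise DivergentIntegralError(
            f"TR release integral diverges: nonpositive force constants {bad}"
        )


def _z_radial(r0: float, k: float, RT: float, epsrel: float) -> float:
    sigma = math.sqrt(RT / k)
    lo, hi = max(0.0, r0 - 10.0 * sigma), r0 + 10.0 * sigma
    val, _ = quad(lambda r: r * r * math.exp(-0.5 * k * (r - r0) ** 2 / RT),
                  lo, hi, epsabs=0.0, epsrel=epsrel, limit=200)
    return val


def _z_polar(theta0_deg: float, k: float, RT: float, epsrel: float) -> float:
    theta0 = math.radians(theta0_deg)
    val, _ = quad(lambda t: math.sin(t) * math.exp(-0.5 * k * (t - theta0) ** 2 / RT),
                  0.0, math.pi, epsabs=0.0, epsrel=epsrel, limit=200,
                  points=[theta0])
    return val


def _z_dihedral(k: float, RT: float, epsrel: float) -> float:
    # Full-period integral of exp(-k ξ²/2RT) with the difference wrapped to
    # (-π, π]; independent of the reference value. For narrow wells
    # (σ < 5°) the Gaussian integral is exact to machine precision.
    sigma = math.sqrt(RT / k)
    if sigma < math.radians(5.0):
        return math.sqrt(2.0 * math.pi * RT / k)
    val, _ = quad(lambda x: math.exp(-0.5 * k * x * x / RT),
                  -math.pi, math.pi, epsabs=0.0, epsrel=epsrel, limit=200)
    return val


def tr_configuration_integral(
    tr: TRRestraint,
    temperature: float = T_DEFAULT,
    epsrel: float = 1e-9,
) -> float:
    """Z_TR by factorised adaptive quadrature (Å³·rad³)."""
    _check_force_constants(tr)
    RT = rt(temperature)
    z = _z_radial(tr.r0, tr.k_r, RT, epsrel)
    z *= _z_polar(tr.theta0, tr.k_theta, RT, epsrel)
    z *= _z_polar(tr.Theta0, tr.k_Theta, RT, epsrel)
    for k in (tr.k_phi, tr.k_Phi, tr.k_Psi):
        z *= _z_dihedral(k, RT, epsrel)
    if not np.isfinite(z) or z <= 0:
        raise DivergentIntegralError("TR configurational integral did not evaluate to a finite positive value")
    return z


def tr_configuration_integral_stiff(tr: TRRestraint, temperature: float = T_DEFAULT) -> float:
    """Stiff-spring (Gaussian) closed form of Z_TR."""
    _check_force_constants(tr)
    RT = rt(temperature)
    k_product = math.prod(tr.force_constants)
    return (tr.r0 ** 2
            * math.sin(math.radians(tr.theta0))
            * math.sin(math.radians(tr.Theta0))
            * (2.0 * math.pi * RT) ** 3
            / math.sqrt(k_product))


def tr_release_free_energy(
    tr: TRRestraint,
    temperature: float = T_DEFAULT,
    method: str = "quadrature",
    standard_state: StandardState = StandardState(),
    epsrel: float = 1e-9,
) -> float:
    """ΔG of releasing the TR restraints to 1 M standard concentration.

    ``method`` is "quadrature" (default; exact up to the integration
    tolerance) or "stiff_spring" (Boresch closed form, valid when θ0 and Θ0
    are many σ away from 0°/180° and the distance well excludes r = 0).
    Returns kcal/mol; negative for tight restraints.
    """
    if method == "quadrature":
        z = tr_configuration_integral(tr, temperature, epsrel)
    elif method == "stiff_spring":
        z = tr_configuration_integral_stiff(tr, temperature)
    else:
        raise ValueError(f"unknown method {method!r}; use 'quadrature' or 'stiff_spring'")
    RT = rt(temperature)
    return -RT * math.log(standard_state.orientational_volume * standard_state.V0 / z)
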