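"""Per-channel rate constants.

Conventional transition state theory with a multiplicative tunneling
correction gives the thermal (activation-controlled) rate

    k_act = sigma * kappa * (k_B T / h) * exp(-dG_act / (R T)),

with the barrier in kcal/mol.  The tunneling coefficient is either supplied
directly or computed as the thermally averaged transmission through a 1-D
asymmetric Eckart barrier.  Electron-transfer barriers come from Marcus
theory.  Fast reactions are capped by diffusion: the Smoluchowski encounter
rate with Stokes-Einstein diffusion coefficients supplies k_D, and the
Collins-Kimball interpolation k_app = k_D k_act / (k_D + k_act) yields the
apparent rate constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.integrate import quad

from .constants import (
    CONSTANTS,
    JOULES_PER_KCAL,
    JOULES_PER_WAVENUMBER,
    PhysicalConstants,
)
from .profiles_io import EckartParameters, MarcusInput, Medium, ReactionChannel

#: Default hydrodynamic radius (Angstrom) for each diffusing partner when a
#: medium does not override the diffusion limit explicitly.
DEFAULT_RADIUS_A = 2.0


class KineticsError(ValueError):
    """Invalid kinetic input (negative tunneling, non-positive lambda, ...)."""


@dataclass(frozen=True)
class RateEvaluation:
    """Outcome of evaluating one channel.

    ``apparent_rate`` never exceeds either ``thermal_rate`` or
    ``diffusion_rate`` (Collins-Kimball bound).
    """

    thermal_rate: float
    diffusion_rate: float
    apparent_rate: float
    tunneling_used: Optional[float] = None
    barrier_used: Optional[float] = None


def tst_rate(
    activation_free_energy: float,
    tunneling: float = 1.0,
    symmetry_number: int = 1,
    temperature: float | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Eyring rate sigma*kappa*(k_B T/h)*exp(-dG_act/RT).

    Units follow the prefactor: 1/s for a unimolecular standard state, and
    the conventional M^-1 s^-1 reading for the bimolecular channels handled
    here (the 1 M standard state is already folded into dG_act).
    """
    if tunneling <= 0:
        raise KineticsError("tunneling coefficient must be positive")
    if symmetry_number < 1:
        raise KineticsError("symmetry number must be >= 1")
    rt = constants.rt(temperature)
    if rt <= 0:
        raise KineticsError("temperature must be positive")
    prefactor = constants.thermal_frequency(temperature)
    return symmetry_number * tunneling * prefactor * math.exp(-activation_free_energy / rt)


def tst_barrier(
    rate: float,
    tunneling: float = 1.0,
    symmetry_number: int = 1,
    temperature: float | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Invert :func:`tst_rate`: the barrier (kcal/mol) that reproduces ``rate``."""
    if rate <= 0:
        raise KineticsError("rate must be positive to invert")
    prefactor = symmetry_number * tunneling * constants.thermal_frequency(temperature)
    return -constants.rt(temperature) * math.log(rate / prefactor)


# ---------------------------------------------------------------------------
# Eckart tunneling
# ---------------------------------------------------------------------------


def _logsinh(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(x > 0, x - math.log(2.0) + np.log1p(-np.exp(-2.0 * x)), -np.inf)


def _logcosh(x: np.ndarray) -> np.ndarray:
    x = np.abs(np.asarray(x, dtype=float))
    return x - math.log(2.0) + np.log1p(np.exp(-2.0 * x))


def eckart_log_transmission(
    energy_j: np.ndarray,
    forward_barrier_j: float,
    reverse_barrier_j: float,
    frequency_cm: float,
) -> np.ndarray:
    """log of the transmission probability P(E) for the asymmetric Eckart
    barrier, with energies in J per molecule measured from the reactants.

    Uses the standard dimensionless parameterisation
    alpha_i = 2*pi*V_i / (h*c*omega); evaluated in log space so thick
    barriers (alpha of a few hundred) do not overflow.  P = 0 below the
    product asymptote V1 - V2.
    """
    quantum = JOULES_PER_WAVENUMBER * frequency_cm
    a1 = 2.0 * math.pi * forward_barrier_j / quantum
    a2 = 2.0 * math.pi * reverse_barrier_j / quantum
    denom = 1.0 / math.sqrt(a1) + 1.0 / math.sqrt(a2)
    xi = np.asarray(energy_j, dtype=float) / forward_barrier_j
    a = 2.0 * np.sqrt(np.clip(a1 * xi, 0.0, None)) / denom
    open_channel = (xi - 1.0) * a1 + a2
    b = 2.0 * np.sqrt(np.clip(open_channel, 0.0, None)) / denom
    disc = a1 * a2 - math.pi**2 / 4.0
    log_num = math.log(2.0) + _logsinh(a) + _logsinh(b)
    if disc >= 0.0:
        log_den = np.logaddexp(_logcosh(a + b), _logcosh(2.0 * math.sqrt(disc)))
    else:
        cos_term = math.cos(2.0 * math.sqrt(-disc))
        lc = _logcosh(a + b)
        log_den = lc + np.log1p(cos_term * np.exp(-lc))
    out = log_num - log_den
    return np.where(open_channel > 0.0, out, -np.inf)


def eckart_kappa(
    params: EckartParameters,
    temperature: float | None = None,
    rel_tol: float = 1e-8,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Thermally averaged Eckart transmission coefficient.

    kappa = (1/k_B T) * integral_0^inf P(E) exp(-(E - V1)/k_B T) dE,
    integrated adaptively from the product asymptote up to V1 + 40 k_B T
    (the Boltzmann weight beyond that bound is ~4e-18 of the maximum).
    Approaches 1 as the imaginary frequency goes to zero.
    """
    t = constants.default_temperature if temperature is None else temperature
    if t <= 0:
        raise KineticsError("temperature must be positive")
    v1 = params.forward_barrier * JOULES_PER_KCAL / constants.avogadro_number
    v2 = params.reverse_barrier * JOULES_PER_KCAL / constants.avogadro_number
    kt = constants.boltzmann_constant * t

    def integrand(energy: float) -> float:
        log_p = float(
            eckart_log_transmission(
                np.array([energy]), v1, v2, params.imaginary_frequency
            )[0]
        )
        if not math.isfinite(log_p):
            return 0.0
        return math.exp(log_p + (v1 - energy) / kt)

    lower = max(0.0, v1 - v2)
    upper = v1 + 40.0 * kt
    value, err = quad(
        integrand,
        lower,
        upper,
        points=[v1] if lower < v1 < upper else None,
        limit=300,
        epsabs=0.0,
        epsrel=rel_tol,
    )
    if not math.isfinite(value) or (value > 0 and err / value > 1e-4):
        raise KineticsError(
            f"Eckart quadrature did not converge (value={value!r}, err={err!r}, "
            f"V1={params.forward_barrier}, V2={params.reverse_barrier}, "
            f"omega={params.imaginary_frequency}, T={t})"
        )
    return value / kt


# ---------------------------------------------------------------------------
# Marcus theory
# ---------------------------------------------------------------------------


def marcus_barrier(marcus: MarcusInput | None = None, *, reorganization_energy: float | None = None, reaction_free_energy: float | None = None) -> float:
    """Marcus activation free energy dG_act = (lambda/4)(1 + dG0/lambda)^2.

    Accepts either a :class:`MarcusInput` or the two keyword scalars, all in
    kcal/mol.  Zero at dG0 = -lambda and rising again beyond it (inverted
    region).
    """
    if marcus is not None:
        lam = marcus.reorganization_energy
        dg0 = marcus.reaction_free_energy
    else:
        lam = reorganization_energy
        dg0 = reaction_free_energy
    if lam is None or dg0 is None:
        raise KineticsError("marcus_barrier needs lambda and dG0")
    if lam <= 0:
        raise KineticsError("reorganization energy must be positive")
    return (lam / 4.0) * (1.0 + dg0 / lam) ** 2


SignConvention = Literal["plus", "minus"]


def marcus_lambda(
    vertical_energy_gap: float,
    reaction_free_energy: float,
    sign_convention: SignConvention = "plus",
) -> float:
    """Reorganization energy from the vertical gap and the reaction free energy.

    Two sign conventions circulate for lambda ~ dE_SET -/+ dG0_SET; both are
    offered.  A non-positive result raises, advising the other convention.
    """
    if not (math.isfinite(vertical_energy_gap) and math.isfinite(reaction_free_energy)):
        raise KineticsError("marcus_lambda requires finite inputs")
    if sign_convention == "plus":
        lam = vertical_energy_gap + reaction_free_energy
        other = "minus"
    elif sign_convention == "minus":
        lam = vertical_energy_gap - reaction_free_energy
        other = "plus"
    else:
        raise KineticsError(f"unknown sign convention {sign_convention!r}")
    if lam <= 0:
        raise KineticsError(
            f"non-positive reorganization energy ({lam} kcal/mol) under "
            f"{sign_convention}; consider sign_convention={other!r}"
        )
    return lam


# ---------------------------------------------------------------------------
# Diffusion limits
# ---------------------------------------------------------------------------


def smoluchowski_kd(
    radius_a: float,
    radius_b: float,
    viscosity: float,
    temperature: float | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Steady-state Smoluchowski encounter rate in M^-1 s^-1.

    k_D = 4 pi (r_a + r_b) (D_a + D_b) N_A with Stokes-Einstein diffusion
    coefficients D_i = k_B T / (6 pi eta r_i); radii in Angstrom, viscosity
    in Pa*s.
    """
    if radius_a <= 0 or radius_b <= 0:
        raise KineticsError("radii must be positive")
    if viscosity <= 0:
        raise KineticsError("viscosity must be positive")
    t = constants.default_temperature if temperature is None else temperature
    ra = radius_a * 1e-10
    rb = radius_b * 1e-10
    diffusion = constants.boltzmann_constant * t / (6.0 * math.pi * viscosity)
    d_ab = diffusion / ra + diffusion / rb
    kd_m3 = 4.0 * math.pi * (ra + rb) * d_ab * constants.avogadro_number
    return kd_m3 * 1000.0  # m^3/(mol s) -> L/(mol s)


def collins_kimball(thermal_rate: float, diffusion_rate: float) -> float:
    """Collins-Kimball apparent rate k_D k_act / (k_D + k_act).

    Bounded above by both inputs; returns 0 when both are 0 and the finite
    partner's limit when one is infinite.
    """
    if thermal_rate < 0 or diffusion_rate < 0:
        raise KineticsError("rates must be non-negative")
    if thermal_rate == 0 and diffusion_rate == 0:
        return 0.0
    if math.isinf(diffusion_rate):
        return thermal_rate
    if math.isinf(thermal_rate):
        return diffusion_rate
    total = thermal_rate + diffusion_rate
    if total == 0:
        return 0.0
    return diffusion_rate * thermal_rate / total


# ---------------------------------------------------------------------------
# Channel evaluation
# ---------------------------------------------------------------------------

RatePolicy = Literal["printed", "recompute"]


def medium_diffusion_limit(
    medium: Medium, radical: str, temperature: float | None = None
) -> float:
    """Diffusion-limited rate for a radical in a medium: the per-radical
    override when supplied, else the Smoluchowski/Stokes-Einstein estimate
    with default radii."""
    if medium.diffusion_limit_override:
        if radical in medium.diffusion_limit_override:
            return medium.diffusion_limit_override[radical]
        if "*" in medium.diffusion_limit_override:
            return medium.diffusion_limit_override["*"]
    return smoluchowski_kd(
        DEFAULT_RADIUS_A, DEFAULT_RADIUS_A, medium.viscosity, temperature
    )


def channel_tunneling(
    channel: ReactionChannel, temperature: float | None = None
) -> float:
    """Transmission coefficient for a channel: a supplied scalar, a computed
    Eckart average, or 1 when neither is given."""
    if isinstance(channel.tunneling, EckartParameters):
        return eckart_kappa(channel.tunneling, temperature)
    if channel.tunneling is None:
        return 1.0
    return float(channel.tunneling)


def evaluate_channel(
    channel: ReactionChannel,
    medium: Medium,
    temperature: float | None = None,
    policy: RatePolicy = "printed",
) -> RateEvaluation:
    """Apparent rate constant for one reaction channel.

    ``policy="printed"`` prefers a ``fixed_rate`` carried by the channel
    (table transcriptions); ``policy="recompute"`` prefers re-deriving the
    rate from the channel's barrier/tunneling or Marcus parameters, falling
    back to ``fixed_rate`` only when no parameters are present.
    """
    kd = medium_diffusion_limit(medium, channel.radical, temperature)

    def fixed() -> RateEvaluation:
        rate = float(channel.fixed_rate)  # type: ignore[arg-type]
        return RateEvaluation(
            thermal_rate=rate,
            diffusion_rate=math.inf,
            apparent_rate=rate,
            tunneling_used=None,
            barrier_used=channel.activation_free_energy,
        )

    has_params = (
        channel.barrierless
        or channel.activation_free_energy is not None
        or channel.marcus is not None
    )
    if channel.fixed_rate is not None and (policy == "printed" or not has_params):
        return fixed()

    if channel.barrierless:
        return RateEvaluation(
            thermal_rate=math.inf,
            diffusion_rate=kd,
            apparent_rate=kd,
            tunneling_used=None,
            barrier_used=0.0,
        )
    if channel.mechanism == "SET":
        if channel.marcus is None:
            return fixed()
        barrier = marcus_barrier(channel.marcus)
        thermal = tst_rate(barrier, 1.0, channel.symmetry_number, temperature)
        return RateEvaluation(
            thermal_rate=thermal,
            diffusion_rate=kd,
            apparent_rate=collins_kimball(thermal, kd),
            tunneling_used=1.0,
            barrier_used=barrier,
        )
    kappa = channel_tunneling(channel, temperature)
    barrier = channel.activation_free_energy
    assert barrier is not None  # guaranteed by the schema validator
    thermal = tst_rate(barrier, kappa, channel.symmetry_number, temperature)
    return RateEvaluation(
        thermal_rate=thermal,
        diffusion_rate=kd,
        apparent_rate=collins_kimball(thermal, kd),
        tunneling_used=kappa,
        barrier_used=barrier,
    )
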