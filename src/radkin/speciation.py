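"""Acid-base speciation: pKa from reaction free energies and equilibrium
mole fractions of the protonation states at a given pH.

The compound is treated as a polyprotic acid with macroscopic pKa values
only (no site-resolved tautomers).  With states ordered most-protonated
first, the population of state j at a given pH is proportional to
``10 ** sum_{i<=j} (pH - pKa_i)`` -- the multi-step generalisation of the
Henderson-Hasselbalch relation.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .profiles_io import AcidBaseSystem

#: Default physiological pH used throughout the package.
PHYSIOLOGICAL_PH = 7.4

#: Default additive reference constant for the hydroxide-exchange pKa
#: scheme (AH + OH- -> A- + H2O referenced through pK_w = 14).
DEFAULT_PKA_REFERENCE = 14.0


def pka_from_energy(
    delta_g_sol: float,
    temperature: float | None = None,
    reference_constant: float = DEFAULT_PKA_REFERENCE,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """pKa from the solution free energy of the proton-exchange reaction.

    pKa = dG_sol / (R*T*ln 10) + reference_constant, with ``delta_g_sol`` in
    kcal/mol.  The additive constant encodes the thermodynamic reference of
    the exchange scheme (14 for hydroxide exchange via pK_w).
    """
    if not (math.isfinite(delta_g_sol) and math.isfinite(reference_constant)):
        raise ValueError("pka_from_energy requires finite inputs")
    rt = constants.rt(temperature)
    if rt <= 0:
        raise ValueError("temperature must be positive")
    return delta_g_sol / (rt * math.log(10.0)) + reference_constant


def energy_for_pka(
    pka: float,
    temperature: float | None = None,
    reference_constant: float = DEFAULT_PKA_REFERENCE,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Inverse of :func:`pka_from_energy`: dG_sol (kcal/mol) for a target pKa."""
    rt = constants.rt(temperature)
    return (pka - reference_constant) * rt * math.log(10.0)


def mole_fractions(
    acid_base: AcidBaseSystem | Sequence[float], ph: float
) -> np.ndarray:
    """Equilibrium fractions of each protonation state, most-protonated first.

    Accepts an :class:`AcidBaseSystem` or a bare ascending pKa sequence and
    returns ``len(pka) + 1`` fractions that sum to 1.  Computed via a
    log-space softmax so extreme pH values cannot overflow.
    """
    if isinstance(acid_base, AcidBaseSystem):
        pka = list(acid_base.pka_values)
    else:
        pka = list(acid_base)
        if any(b <= a for a, b in zip(pka, pka[1:])):
            raise ValueError("pKa values must be strictly ascending")
    if not math.isfinite(ph):
        raise ValueError("ph must be finite")
    exponents = np.concatenate(([0.0], np.cumsum([ph - p for p in pka])))
    exponents -= exponents.max()
    weights = np.power(10.0, exponents)
    return weights / weights.sum()


def percent(fraction: float, decimals: int = 2) -> float:
    """Fraction as a percentage, rounded half-up (table formatting)."""
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(repr(float(fraction))) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


def speciation_summary(
    acid_base: AcidBaseSystem, ph: float = PHYSIOLOGICAL_PH
) -> list[tuple[str, float, float]]:
    """(label, fraction, rounded percent) per state at the given pH."""
    fractions = mole_fractions(acid_base, ph)
    return [
        (label, float(f), percent(float(f)))
        for label, f in zip(acid_base.state_labels, fractions)
    ]
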