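"""Physical constants used throughout the kinetics pipeline.

Energies are carried in kcal/mol everywhere in this package; conversion to
SI happens only inside the rate and tunneling evaluations.  All values come
from :mod:`scipy.constants` (CODATA).
"""

from __future__ import annotations

from dataclasses import dataclass

import scipy.constants as _sc

#: Joules per kcal (thermochemical calorie).
JOULES_PER_KCAL: float = _sc.calorie * 1000.0

#: Joules per wavenumber quantum, h*c with c in cm/s.
JOULES_PER_WAVENUMBER: float = _sc.h * _sc.c * 100.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants plus the default working temperature.

    Attributes
    ----------
    boltzmann_constant : float
        k_B in J/K.
    planck_constant : float
        h in J*s.
    gas_constant : float
        R in kcal/(mol*K) -- the unit every barrier in this package uses.
    avogadro_number : float
        N_A in 1/mol.
    default_temperature : float
        298.15 K, the temperature at which all reported rates are evaluated.
    """

    boltzmann_constant: float = _sc.k
    planck_constant: float = _sc.h
    gas_constant: float = _sc.R / JOULES_PER_KCAL
    avogadro_number: float = _sc.N_A
    default_temperature: float = 298.15

    def rt(self, temperature: float | None = None) -> float:
        """R*T in kcal/mol at ``temperature`` (default 298.15 K)."""
        t = self.default_temperature if temperature is None else temperature
        return self.gas_constant * t

    def thermal_frequency(self, temperature: float | None = None) -> float:
        """Eyring prefactor k_B*T/h in 1/s (~6.21e12 at 298.15 K)."""
        t = self.default_temperature if temperature is None else temperature
        return self.boltzmann_constant * t / self.planck_constant


CONSTANTS = PhysicalConstants()
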