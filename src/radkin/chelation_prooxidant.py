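"""Metal chelation equilibria and pro-oxidant electron-transfer kinetics.

Chelation of a metal aqua complex by an antioxidant ligand state,

    [M(H2O)6]^n + A^m  <=>  [M(H2O)4 A]^(n-m) + 2 H2O,

is characterised by the formation constant K_f = exp(-dG_f / RT).  Because
only a fraction of the ligand is in the chelation-active protonation state
at a given pH, the speciation-corrected constant is K^II = K_f * f and the
apparent constant K^app sums K^II over ligand states.

The resulting complexes can act as pro-oxidants by accepting an electron
from physiological reductants (ascorbate, superoxide).  Those steps are
modelled as outer-sphere electron transfers: Marcus barrier from
(lambda, dG_r), Eyring rate with kappa = 1, and a Collins-Kimball diffusion
correction against the aqueous diffusion limit of the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import yaml

from .constants import CONSTANTS, PhysicalConstants
from .kinetics_core import RateEvaluation, collins_kimball, marcus_barrier, tst_rate
from .profiles_io import MarcusInput, ProfileParseError, SpeciesState


@dataclass(frozen=True)
class ComplexationReaction:
    """One metal-ligand complexation with its free energy (kcal/mol)."""

    metal: str
    metal_charge: int
    ligand_state: SpeciesState
    denticity: Literal["mono", "bi"]
    complexation_free_energy: float


@dataclass(frozen=True)
class ComplexationResult:
    """K_f, the mole-fraction-corrected K^II values, and K^app = sum(K^II)."""

    formation_constant: float
    corrected_constants: tuple[float, ...]
    apparent_constant: float


@dataclass(frozen=True)
class RedoxStep:
    """Single-electron transfer from a reductant to a metal complex."""

    complex_label: str
    reductant: str
    marcus: MarcusInput
    rate: Optional[RateEvaluation] = None


def formation_constant(
    delta_g: float,
    temperature: float | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Equilibrium constant K_f = exp(-dG / RT), dG in kcal/mol."""
    return math.exp(-delta_g / constants.rt(temperature))


def apparent_constant(pairs: Iterable[tuple[float, float]]) -> float:
    """K^app = sum of K_f,i * f_i over ligand states; 0 for an empty list."""
    total = 0.0
    for k_f, fraction in pairs:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"mole fraction {fraction!r} outside [0, 1]")
        total += k_f * fraction
    return total


def complexation_result(
    reactions: Sequence[ComplexationReaction],
    temperature: float | None = None,
) -> ComplexationResult:
    """Evaluate K_f per reaction and the speciation-corrected aggregate.

    Each reaction's ligand state must carry its mole fraction; K^II uses it
    and K^app sums the corrected constants.  The returned
    ``formation_constant`` is the largest single K_f (the dominant complex).
    """
    k_fs = [formation_constant(r.complexation_free_energy, temperature) for r in reactions]
    corrected = []
    for r, k_f in zip(reactions, k_fs):
        f = r.ligand_state.mole_fraction
        if f is None:
            raise ValueError(
                f"ligand state {r.ligand_state.label!r} has no mole fraction"
            )
        corrected.append(k_f * f)
    return ComplexationResult(
        formation_constant=max(k_fs, default=0.0),
        corrected_constants=tuple(corrected),
        apparent_constant=math.fsum(corrected),
    )


def prooxidant_rate(
    step: RedoxStep | MarcusInput,
    diffusion_rate: float,
    temperature: float | None = None,
) -> RateEvaluation:
    """Marcus + TST + Collins-Kimball rate for one pro-oxidant SET step.

    ``diffusion_rate`` is the aqueous diffusion limit (M^-1 s^-1) for this
    reductant/complex pair; the apparent rate never exceeds it.
    """
    marcus = step.marcus if isinstance(step, RedoxStep) else step
    barrier = marcus_barrier(marcus)
    thermal = tst_rate(barrier, tunneling=1.0, symmetry_number=1, temperature=temperature)
    return RateEvaluation(
        thermal_rate=thermal,
        diffusion_rate=diffusion_rate,
        apparent_rate=collins_kimball(thermal, diffusion_rate),
        tunneling_used=1.0,
        barrier_used=barrier,
    )


@dataclass(frozen=True)
class ComplexSet:
    """A metal/ligand complexation study: formation reactions plus the
    pro-oxidant redox steps of the resulting complexes.

    ``printed_*`` lists carry published reference values when the set was
    transcribed from a table (empty otherwise); ``diffusion_limits`` holds
    one aqueous diffusion limit per redox step, back-solved from the printed
    (thermal, apparent) rate pair when not stated explicitly.
    """

    metal: str
    metal_charge: int
    monoanion_fraction: float
    complexations: list[ComplexationReaction]
    redox_steps: list[RedoxStep]
    diffusion_limits: list[float]
    printed_constants: list[float] = field(default_factory=list)
    printed_barriers: list[float] = field(default_factory=list)
    printed_thermal_rates: list[float] = field(default_factory=list)
    printed_apparent_rates: list[float] = field(default_factory=list)


def parse_complex_set(raw: dict, source: str = "<dict>") -> ComplexSet:
    """Build a :class:`ComplexSet` from the YAML mapping layout used by the
    bundled copper fixture (``complexation`` and ``redox`` row lists)."""
    try:
        ligand = SpeciesState(
            label="monoanion", charge=-1, mole_fraction=raw["monoanion_fraction"]
        )
        complexations = [
            ComplexationReaction(
                metal=raw["metal"],
                metal_charge=raw["metal_charge"],
                ligand_state=ligand,
                denticity=row["denticity"],
                complexation_free_energy=row["delta_g"],
            )
            for row in raw.get("complexation", [])
        ]
        steps, kds = [], []
        for row in raw.get("redox", []):
            steps.append(
                RedoxStep(
                    complex_label=row["complex"],
                    reductant=row["reductant"],
                    marcus=MarcusInput(
                        reorganization_energy=row["lambda"],
                        reaction_free_energy=row["dg_r"],
                    ),
                )
            )
            if "diffusion_limit" in row:
                kds.append(float(row["diffusion_limit"]))
            else:
                kds.append(1.0 / (1.0 / row["printed_k_app"] - 1.0 / row["printed_k"]))
        return ComplexSet(
            metal=raw["metal"],
            metal_charge=raw["metal_charge"],
            monoanion_fraction=raw["monoanion_fraction"],
            complexations=complexations,
            redox_steps=steps,
            diffusion_limits=kds,
            printed_constants=[
                row["printed_constant"]
                for row in raw.get("complexation", [])
                if "printed_constant" in row
            ],
            printed_barriers=[
                row["printed_dg_act"] for row in raw.get("redox", []) if "printed_dg_act" in row
            ],
            printed_thermal_rates=[
                row["printed_k"] for row in raw.get("redox", []) if "printed_k" in row
            ],
            printed_apparent_rates=[
                row["printed_k_app"] for row in raw.get("redox", []) if "printed_k_app" in row
            ],
        )
    except (KeyError, TypeError) as exc:
        raise ProfileParseError(f"{source}: malformed complexation set: {exc}") from exc


def read_complex_set(path: str | Path) -> ComplexSet:
    """Read a complexation/redox YAML document (see the bundled copper
    fixture for the layout)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ProfileParseError(f"{path}: {exc}") from exc
    return parse_complex_set(raw, str(path))


def redox_table(
    steps: Sequence[RedoxStep],
    diffusion_rates: Sequence[float],
    temperature: float | None = None,
) -> list[dict]:
    """Rows (complex, reductant, lambda, dG_r, dG_act, k, k_app) for a set of
    pro-oxidant steps; mirrors the layout of complex-redox kinetics tables."""
    if len(steps) != len(diffusion_rates):
        raise ValueError("need one diffusion rate per redox step")
    rows = []
    for step, kd in zip(steps, diffusion_rates):
        rate = prooxidant_rate(step, kd, temperature)
        rows.append(
            {
                "complex": step.complex_label,
                "reductant": step.reductant,
                "lambda": step.marcus.reorganization_energy,
                "dG_r": step.marcus.reaction_free_energy,
                "dG_act": rate.barrier_used,
                "k": rate.thermal_rate,
                "k_app": rate.apparent_rate,
            }
        )
    return rows
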