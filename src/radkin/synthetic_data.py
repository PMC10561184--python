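"""Synthetic antioxidant profiles and the bundled transcription fixtures.

The generator emits profiles with the statistical structure the pipeline
assumes -- a polyprotic phenol with several hydrogen-donating sites, FHT and
RAF channels in both media, SET channels for the anions in water, barrier
and reorganization-energy ranges matching what is observed for phenolic
antioxidants reacting with oxygenated radicals -- so every stage is testable
without any external download.  Generation is fully deterministic for a
fixed seed.

:func:`reference_fixtures` returns the transcribed kinetics tables bundled with
the package (two alkylresorcinols against HO and HOO in water and pentyl
ethanoate, plus the copper chelation/redox set) together with their expected
aggregate outputs for regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .chelation_prooxidant import ComplexSet, parse_complex_set
from .profiles_io import (
    AcidBaseSystem,
    AntioxidantProfile,
    EckartParameters,
    MarcusInput,
    Medium,
    ReactionChannel,
    SpeciesState,
    read_profile,
)

_STATE_LABELS = ["neutral", "monoanion", "dianion", "trianion"]


class GeneratorConfig(BaseModel):
    """Knobs for the synthetic-profile generator.

    Defaults mirror the conditions of the bundled study fixtures: barriers
    of a few to ~25 kcal/mol for hydrogen transfer toward HOO, SET
    reorganization energies of 5-45 kcal/mol, up to three pKa values in the
    3-12 window, and water (pH 7.4) plus a lipid ester as media.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_sites: int = Field(default=3, ge=1, le=6)
    barrier_range: tuple[float, float] = (2.0, 25.0)
    lambda_range: tuple[float, float] = (5.0, 45.0)
    pka_count: int = Field(default=2, ge=0, le=3)
    pka_range: tuple[float, float] = (3.0, 12.0)
    media: Optional[list[Medium]] = None
    exergonic_fraction: float = Field(default=0.8, ge=0.0, le=1.0)
    radical: str = "HOO"
    #: "eckart" samples Eckart barrier parameters; "fixed" samples a plain
    #: transmission coefficient.  Both ingestion paths are exercised.
    kappa_mode: str = Field(default="eckart", pattern="^(eckart|fixed)$")

    @model_validator(mode="after")
    def _ranges(self) -> "GeneratorConfig":
        for name in ("barrier_range", "lambda_range", "pka_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a non-degenerate interval")
        return self


def _default_media(aqueous: bool) -> list[Medium]:
    media = [Medium(name="pentyl ethanoate", is_aqueous=False, viscosity=8.62e-4)]
    if aqueous:
        media.insert(
            0, Medium(name="water", is_aqueous=True, ph=7.4, viscosity=8.91e-4)
        )
    return media


def generate_profile(config: GeneratorConfig) -> AntioxidantProfile:
    """Generate a random, schema-valid antioxidant profile.

    Deterministic for a fixed config (seeded generator); with ``pka_count``
    = 0 only the lipid medium is emitted, so every channel runs at f = 1.
    When ``n_sites`` >= 2 and an aqueous medium is present, at least one
    channel of each mechanism (FHT, RAF, SET) is produced.
    """
    rng = np.random.default_rng(config.seed)
    n_states = config.pka_count + 1
    if config.pka_count:
        lo, hi = config.pka_range
        raw = np.sort(rng.uniform(lo, hi, size=config.pka_count))
        # enforce strict ascent with a minimal spacing of 0.5 pKa units
        pka = [float(raw[0])]
        for value in raw[1:]:
            pka.append(float(max(value, pka[-1] + 0.5)))
    else:
        pka = []
    acid_base = AcidBaseSystem(
        pka_values=pka, state_labels=_STATE_LABELS[:n_states]
    )
    states = [
        SpeciesState(label=label, charge=-i)
        for i, label in enumerate(acid_base.state_labels)
    ]
    media = config.media or _default_media(aqueous=config.pka_count > 0)
    aqueous = [m for m in media if m.is_aqueous]

    def sample_dg_r() -> float:
        if rng.random() < config.exergonic_fraction:
            return float(rng.uniform(-30.0, -1.0))
        return float(rng.uniform(0.5, 10.0))

    def sample_tunneling(barrier: float):
        if config.kappa_mode == "fixed":
            return float(rng.uniform(1.0, 200.0))
        reverse = barrier + float(rng.uniform(0.5, 15.0))
        return EckartParameters(
            forward_barrier=max(barrier, 0.5),
            reverse_barrier=reverse,
            imaginary_frequency=float(rng.uniform(800.0, 3200.0)),
        )

    channels: list[ReactionChannel] = []
    b_lo, b_hi = config.barrier_range
    for medium in media:
        reacting_state = acid_base.state_labels[0]
        for site_index in range(config.n_sites):
            site = f"{site_index + 1}OH" if site_index % 2 == 0 else f"{site_index + 1}CH"
            barrier = float(rng.uniform(b_lo, b_hi))
            channels.append(
                ReactionChannel(
                    mechanism="FHT",
                    site=site,
                    radical=config.radical,
                    medium=medium.name,
                    species_state=reacting_state,
                    activation_free_energy=barrier,
                    tunneling=sample_tunneling(barrier),
                    reaction_free_energy=sample_dg_r(),
                )
            )
        if config.n_sites >= 2:
            channels.append(
                ReactionChannel(
                    mechanism="RAF",
                    site="C1-C6",
                    radical=config.radical,
                    medium=medium.name,
                    species_state=reacting_state,
                    activation_free_energy=float(rng.uniform(b_lo, b_hi)),
                    reaction_free_energy=sample_dg_r(),
                )
            )
    for medium in aqueous:
        # SET from each deprotonated state; lambda in the configured window,
        # dG0 mostly in the normal region with occasional inverted draws.
        for label in acid_base.state_labels[1:]:
            lam = float(rng.uniform(*config.lambda_range))
            dg0 = float(rng.uniform(-1.2 * lam, 0.0))
            channels.append(
                ReactionChannel(
                    mechanism="SET",
                    site="mol",
                    radical=config.radical,
                    medium=medium.name,
                    species_state=label,
                    marcus=MarcusInput(
                        reorganization_energy=lam, reaction_free_energy=dg0
                    ),
                    reaction_free_energy=dg0,
                )
            )
    return AntioxidantProfile(
        compound=f"synthetic-{config.seed}",
        acid_base=acid_base,
        media=media,
        states=states,
        channels=channels,
    )


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceFixtures:
    """Bundled transcription fixtures: kinetics profiles, the copper
    chelation/redox set, and the expected aggregate outputs."""

    profiles: dict[str, AntioxidantProfile]
    copper: ComplexSet
    expected: dict = field(default_factory=dict)


def _fixture_text(name: str) -> str:
    return (resources.files("radkin") / "fixtures" / name).read_text()


def load_fixture_profile(name: str) -> AntioxidantProfile:
    """Read one bundled profile fixture by stem, e.g. ``"oli_hoo"``."""
    with resources.as_file(resources.files("radkin") / "fixtures" / f"{name}.yaml") as p:
        return read_profile(p, format="yaml")


def reference_fixtures() -> ReferenceFixtures:
    """All bundled transcription fixtures plus expected aggregate outputs."""
    profiles = {
        name: load_fixture_profile(name)
        for name in ("oli_hoo", "olia_hoo", "oli_ho", "olia_ho")
    }
    copper = parse_complex_set(
        yaml.safe_load(_fixture_text("olia_cu.yaml")), "olia_cu.yaml"
    )
    expected = yaml.safe_load(_fixture_text("expected.yaml"))
    return ReferenceFixtures(profiles=profiles, copper=copper, expected=expected)
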