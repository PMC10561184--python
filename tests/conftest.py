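import pytest
from hypothesis import HealthCheck, settings

import radkin

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixtures():
    """Bundled transcription fixtures (profiles + copper set + expectations)."""
    return radkin.reference_fixtures()


def make_channel(**overrides) -> radkin.ReactionChannel:
    """Minimal valid FHT channel; override any field."""
    base = dict(
        mechanism="FHT",
        site="1OH",
        radical="HOO",
        medium="water",
        species_state="neutral",
        fixed_rate=1.0e6,
    )
    base.update(overrides)
    return radkin.ReactionChannel(**base)


def make_profile(channels=(), pka=(9.9,), fractions=None, **overrides):
    """One-compound profile with water + lipid media for aggregation tests."""
    labels = ["neutral", "monoanion", "dianion", "trianion"][: len(pka) + 1]
    states = []
    for i, label in enumerate(labels):
        f = None if fractions is None else fractions[i]
        states.append(radkin.SpeciesState(label=label, charge=-i, mole_fraction=f))
    base = dict(
        compound="test-compound",
        acid_base=radkin.AcidBaseSystem(pka_values=list(pka), state_labels=labels),
        media=[
            radkin.Medium(name="water", is_aqueous=True, ph=7.4),
            radkin.Medium(name="lipid", is_aqueous=False, viscosity=8.62e-4),
        ],
        states=states,
        channels=list(channels),
    )
    base.update(overrides)
    return radkin.AntioxidantProfile(**base)
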