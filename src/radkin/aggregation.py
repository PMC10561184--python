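"""Assembly of per-channel rates into the per-medium picture.

For each (compound, radical, medium) group the pipeline weights each
channel's apparent rate constant by the equilibrium mole fraction of the
reacting acid-base state (k_f = f * k_app; f = 1 in lipid media, where the
phenolic OH cannot dissociate), computes branching ratios
Gamma_i = 100 * k_f,i / sum(k_f), and reports the overall rate constant as
the plain sum of the weighted rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from . import speciation
from .kinetics_core import RateEvaluation, RatePolicy, evaluate_channel
from .profiles_io import AntioxidantProfile, Medium, ReactionChannel

logger = logging.getLogger(__name__)


class AggregationError(ValueError):
    pass


@dataclass(frozen=True)
class ChannelResult:
    """One evaluated channel: k_app, its weight f, k_f = f*k_app, Gamma (%)."""

    channel: ReactionChannel
    mole_fraction: float
    apparent_rate: float
    weighted_rate: float
    branching_ratio: Optional[float] = None
    evaluation: Optional[RateEvaluation] = None


@dataclass(frozen=True)
class OverallResult:
    """All channels of one compound x radical x medium, plus their sum."""

    compound: str
    radical: str
    medium: str
    channel_results: list[ChannelResult] = field(default_factory=list)
    overall_rate: float = 0.0


def screen_exergonic(
    channels: Iterable[ReactionChannel],
) -> list[ReactionChannel]:
    """Keep channels whose reaction free energy is strictly negative.

    Channels without a recorded dG_r pass through unscreened; dropped
    channels (dG_r >= 0, including the exact-zero boundary) are logged.
    """
    kept = []
    for ch in channels:
        if ch.reaction_free_energy is None or ch.reaction_free_energy < 0:
            kept.append(ch)
        else:
            logger.info(
                "dropping endergonic channel %s %s (%s, %s): dG_r = %+.2f kcal/mol",
                ch.mechanism,
                ch.site,
                ch.species_state,
                ch.medium,
                ch.reaction_free_energy,
            )
    return kept


def weight_channels(
    evaluated: Sequence[tuple[ReactionChannel, RateEvaluation | float]],
    fractions: dict[str, float],
    media: dict[str, Medium],
) -> list[ChannelResult]:
    """Attach mole-fraction weights: k_f = f * k_app.

    ``fractions`` maps state labels to aqueous mole fractions; channels in
    lipid media get f = 1 regardless (no dissociation).  A missing fraction
    for an aqueous channel raises, naming the state.
    """
    results = []
    for channel, rate in evaluated:
        medium = media[channel.medium]
        if not medium.is_aqueous:
            f = 1.0
        else:
            if channel.species_state not in fractions:
                raise AggregationError(
                    f"no mole fraction for state {channel.species_state!r} "
                    f"(channel {channel.mechanism} {channel.site} in {medium.name})"
                )
            f = fractions[channel.species_state]
        if not 0.0 <= f <= 1.0:
            raise AggregationError(
                f"mole fraction {f!r} for state {channel.species_state!r} "
                "outside [0, 1]"
            )
        evaluation = rate if isinstance(rate, RateEvaluation) else None
        k_app = rate.apparent_rate if isinstance(rate, RateEvaluation) else float(rate)
        results.append(
            ChannelResult(
                channel=channel,
                mole_fraction=f,
                apparent_rate=k_app,
                weighted_rate=f * k_app,
                evaluation=evaluation,
            )
        )
    return results


def overall_rate(results: Iterable[ChannelResult]) -> float:
    """Sum of the weighted rates over all channels (0 for an empty list)."""
    return math.fsum(r.weighted_rate for r in results)


def branching_ratios(results: Sequence[ChannelResult]) -> list[ChannelResult]:
    """Gamma_i = 100 * k_f,i / sum(k_f); the unrounded values sum to 100."""
    total = overall_rate(results)
    if results and total <= 0:
        raise AggregationError("branching ratios undefined: all weighted rates are zero")
    return [
        replace(r, branching_ratio=100.0 * r.weighted_rate / total) for r in results
    ]


def aggregate(
    profile: AntioxidantProfile,
    temperature: float | None = None,
    ph: float | None = None,
    policy: RatePolicy = "printed",
    screen: bool = False,
) -> list[OverallResult]:
    """Run speciation -> kinetics -> weighting -> branching for a profile.

    Channels are grouped by (radical, medium) in the order they first
    appear.  Mole fractions are taken from the profile's states when
    supplied, otherwise computed from the pKa ladder at the medium pH (or at
    ``ph`` when given).
    """
    media = {m.name: m for m in profile.media}
    channels = list(profile.channels)
    if screen:
        channels = screen_exergonic(channels)

    fraction_cache: dict[float, dict[str, float]] = {}

    def fractions_at(medium: Medium) -> dict[str, float]:
        use_ph = ph if ph is not None else medium.ph
        if use_ph is None:
            use_ph = speciation.PHYSIOLOGICAL_PH
        if use_ph not in fraction_cache:
            computed = speciation.mole_fractions(profile.acid_base, use_ph)
            table = dict(zip(profile.acid_base.state_labels, map(float, computed)))
            for state in profile.states:
                if state.mole_fraction is not None:
                    table[state.label] = state.mole_fraction
            fraction_cache[use_ph] = table
        return fraction_cache[use_ph]

    groups: dict[tuple[str, str], list[ReactionChannel]] = {}
    for ch in channels:
        groups.setdefault((ch.radical, ch.medium), []).append(ch)

    out = []
    for (radical, medium_name), members in groups.items():
        medium = media[medium_name]
        evaluated = [
            (ch, evaluate_channel(ch, medium, temperature, policy)) for ch in members
        ]
        fractions = fractions_at(medium) if medium.is_aqueous else {}
        results = weight_channels(evaluated, fractions, media)
        total = overall_rate(results)
        if total > 0:
            results = branching_ratios(results)
        out.append(
            OverallResult(
                compound=profile.compound,
                radical=radical,
                medium=medium_name,
                channel_results=results,
                overall_rate=total,
            )
        )
    return out
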