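"""Data model and I/O for antioxidant kinetic profiles and result tables.

A *profile* bundles everything the kinetics pipeline needs for one compound:
its acid-base system (macroscopic pKa ladder), the reaction media, and one
:class:`ReactionChannel` per (mechanism, site, medium, protonation state)
combination.  Profiles are stored as single-document JSON or YAML files, or
as a CSV bundle (a directory with ``profile.csv``, ``media.csv``,
``species.csv`` and ``channels.csv``).

The schema is versioned (``schema: 1``); readers refuse unknown versions and
reject unknown fields so that transcribed fixtures stay stable.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

import pandas as pd
import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

Mechanism = Literal["FHT", "RAF", "SET"]

REPORT_COLUMNS = [
    "mechanism",
    "site",
    "state",
    "dG_act",
    "kappa",
    "k_app",
    "f",
    "k_f",
    "gamma",
    "k_overall",
]


class ProfileError(Exception):
    """Base class for profile I/O failures."""


class ProfileParseError(ProfileError):
    """The file could not be parsed at all (malformed JSON/YAML/CSV)."""


class ProfileValidationError(ProfileError):
    """The file parsed but violates the profile schema or an invariant."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class Medium(_StrictModel):
    """A reaction medium: aqueous (with a pH) or lipid-like.

    ``diffusion_limit_override`` maps a radical label to the diffusion-limited
    rate constant (M^-1 s^-1) to use for barrierless channels and
    Collins-Kimball corrections in this medium; when absent, the
    Smoluchowski/Stokes-Einstein estimate from ``viscosity`` is used.
    """

    name: str
    is_aqueous: bool
    ph: Optional[float] = None
    viscosity: float = Field(default=8.91e-4, gt=0.0)  # Pa*s, water at 298 K
    diffusion_limit_override: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _ph_iff_aqueous(self) -> "Medium":
        if self.is_aqueous and self.ph is None:
            raise ValueError(f"aqueous medium {self.name!r} requires a pH")
        if not self.is_aqueous and self.ph is not None:
            raise ValueError(f"lipid medium {self.name!r} must not carry a pH")
        return self


class SpeciesState(_StrictModel):
    """One acid-base state of the compound (e.g. neutral, monoanion)."""

    label: str
    charge: int
    mole_fraction: Optional[float] = Field(default=None, ge=0.0, le=1.0)


class AcidBaseSystem(_StrictModel):
    """Macroscopic pKa ladder; ``state_labels`` runs most-protonated first."""

    pka_values: list[float] = Field(default_factory=list)
    state_labels: list[str]

    @field_validator("pka_values")
    @classmethod
    def _ascending(cls, v: list[float]) -> list[float]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("pKa values must be strictly ascending")
        return v

    @model_validator(mode="after")
    def _label_count(self) -> "AcidBaseSystem":
        if len(self.state_labels) != len(self.pka_values) + 1:
            raise ValueError(
                f"expected {len(self.pka_values) + 1} state labels for "
                f"{len(self.pka_values)} pKa values, got {len(self.state_labels)}"
            )
        return self


class EckartParameters(_StrictModel):
    """Asymmetric 1-D Eckart barrier: ZPE-corrected forward/reverse barriers
    (kcal/mol) and the transition-state imaginary frequency (cm^-1)."""

    forward_barrier: float = Field(gt=0.0)
    reverse_barrier: float = Field(gt=0.0)
    imaginary_frequency: float = Field(gt=0.0)


class MarcusInput(_StrictModel):
    """Inputs to the Marcus activation barrier for one electron transfer:
    reorganization energy lambda, optional vertical energy gap, and the
    reaction free energy, all in kcal/mol."""

    reorganization_energy: float = Field(gt=0.0)
    vertical_energy_gap: Optional[float] = None
    reaction_free_energy: float


class ReactionChannel(_StrictModel):
    """One elementary scavenging channel.

    ``medium`` and ``species_state`` are references by name/label into the
    owning profile.  Exactly how the rate is obtained depends on mechanism:
    FHT/RAF channels need an activation free energy (kcal/mol), a
    ``barrierless`` flag (diffusion-controlled) or a ``fixed_rate``; SET
    channels need a :class:`MarcusInput` or a ``fixed_rate``.  ``tunneling``
    is either a plain transmission coefficient or Eckart barrier parameters.
    """

    mechanism: Mechanism
    site: str
    radical: str
    medium: str
    species_state: str
    symmetry_number: int = Field(default=1, ge=1)
    activation_free_energy: Optional[float] = None
    tunneling: Union[EckartParameters, float, None] = None
    marcus: Optional[MarcusInput] = None
    reaction_free_energy: Optional[float] = None
    barrierless: bool = False
    fixed_rate: Optional[float] = Field(default=None, ge=0.0)

    @field_validator("tunneling", mode="before")
    @classmethod
    def _zero_kappa_is_absent(cls, v):
        # Tables sometimes print kappa as "0.0" for channels whose true
        # transmission coefficient merely rounds to zero at one decimal; a
        # literal zero would annihilate a rate that is printed as nonzero in
        # the same row, so it is ingested as "not provided".
        if isinstance(v, (int, float)) and not isinstance(v, bool):
            if v == 0:
                logger.warning(
                    "tunneling coefficient 0.0 ingested as absent (defaults to 1.0)"
                )
                return None
            if v < 0:
                raise ValueError("tunneling coefficient must be >= 0")
        return v

    @model_validator(mode="after")
    def _rate_source(self) -> "ReactionChannel":
        ident = f"{self.mechanism} {self.site} ({self.species_state}, {self.medium})"
        if self.mechanism == "SET":
            if self.marcus is None and self.fixed_rate is None:
                raise ValueError(
                    f"SET channel {ident} needs marcus parameters or a fixed_rate"
                )
        else:
            if (
                self.activation_free_energy is None
                and not self.barrierless
                and self.fixed_rate is None
            ):
                raise ValueError(
                    f"{self.mechanism} channel {ident} needs an activation free "
                    "energy, the barrierless flag, or a fixed_rate"
                )
        return self


class ThermoRecord(_StrictModel):
    """Gas-phase thermochemistry bookkeeping for one site.

    ``bde`` (kcal/mol) is derived as H(radical) + H(H atom) - H(parent) when
    the three enthalpies are present; a supplied value must match exactly.
    """

    label: str
    solution_free_energy: Optional[float] = None
    enthalpy_parent: Optional[float] = None
    enthalpy_radical: Optional[float] = None
    enthalpy_h_atom: Optional[float] = None
    bde: Optional[float] = None

    @model_validator(mode="after")
    def _derive_bde(self) -> "ThermoRecord":
        parts = (self.enthalpy_parent, self.enthalpy_radical, self.enthalpy_h_atom)
        if all(p is not None for p in parts):
            derived = self.enthalpy_radical + self.enthalpy_h_atom - self.enthalpy_parent
            if self.bde is None:
                object.__setattr__(self, "bde", derived)
            elif self.bde != derived:
                raise ValueError(
                    f"bde for {self.label!r} is {self.bde}, components give {derived}"
                )
        return self


class AntioxidantProfile(_StrictModel):
    """Root input object: one compound with states, media and channels."""

    schema_version: int = Field(default=SCHEMA_VERSION, alias="schema")
    compound: str
    acid_base: AcidBaseSystem
    media: list[Medium]
    states: list[SpeciesState] = Field(default_factory=list)
    channels: list[ReactionChannel] = Field(default_factory=list)
    gas_phase_thermo: Optional[list[ThermoRecord]] = None

    @model_validator(mode="after")
    def _cross_references(self) -> "AntioxidantProfile":
        labels = set(self.acid_base.state_labels)
        for state in self.states:
            if state.label not in labels:
                raise ValueError(
                    f"species state {state.label!r} not in acid_base.state_labels"
                )
        media_names = {m.name for m in self.media}
        for i, ch in enumerate(self.channels):
            if ch.species_state not in labels:
                raise ValueError(
                    f"channel {i} ({ch.mechanism} {ch.site}): species_state "
                    f"{ch.species_state!r} not in acid_base.state_labels"
                )
            if ch.medium not in media_names:
                raise ValueError(
                    f"channel {i} ({ch.mechanism} {ch.site}): medium "
                    f"{ch.medium!r} not declared in media"
                )
        supplied = [s.mole_fraction for s in self.states if s.mole_fraction is not None]
        if supplied and len(supplied) == len(self.acid_base.state_labels):
            total = math.fsum(supplied)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"supplied mole fractions sum to {total!r}, expected 1"
                )
        return self

    # -- convenience lookups -------------------------------------------------

    def medium_by_name(self, name: str) -> Medium:
        for m in self.media:
            if m.name == name:
                return m
        raise KeyError(name)

    def state_by_label(self, label: str) -> Optional[SpeciesState]:
        for s in self.states:
            if s.label == label:
                return s
        return None


# ---------------------------------------------------------------------------
# Reading and writing profiles
# ---------------------------------------------------------------------------

_CHANNEL_CSV_COLUMNS = [
    "mechanism",
    "site",
    "radical",
    "medium",
    "species_state",
    "symmetry_number",
    "activation_free_energy",
    "kappa",
    "eckart_forward",
    "eckart_reverse",
    "eckart_frequency",
    "marcus_lambda",
    "marcus_vertical_gap",
    "marcus_dg0",
    "reaction_free_energy",
    "barrierless",
    "fixed_rate",
]


def _check_schema(data: dict, source: str) -> None:
    if not isinstance(data, dict):
        raise ProfileParseError(f"{source}: expected a mapping at top level")
    version = data.get("schema", data.get("schema_version"))
    if version is None:
        raise ProfileValidationError(f"{source}: missing 'schema' version field")
    if version != SCHEMA_VERSION:
        raise ProfileValidationError(
            f"{source}: unknown schema version {version!r} (supported: {SCHEMA_VERSION})"
        )


def _validate(data: dict, source: str) -> AntioxidantProfile:
    _check_schema(data, source)
    try:
        return AntioxidantProfile.model_validate(data)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ProfileValidationError(f"{source}: {details}") from exc


def read_profile(
    path: str | Path, format: Literal["json", "yaml", "csv-bundle"] | None = None
) -> AntioxidantProfile:
    """Read and validate an antioxidant profile.

    ``format`` is inferred from the path when omitted: directories are CSV
    bundles, ``.json`` is JSON, anything else is YAML.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "csv-bundle"
        elif path.suffix.lower() == ".json":
            format = "json"
        else:
            format = "yaml"
    if format == "csv-bundle":
        return _read_csv_bundle(path)
    text = path.read_text()
    if format == "json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ProfileParseError(
                f"{path}: line {exc.lineno}, column {exc.colno}: {exc.msg}"
            ) from exc
    else:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f"line {mark.line + 1}" if mark is not None else "unknown position"
            raise ProfileParseError(f"{path}: {where}: {exc}") from exc
    return _validate(data, str(path))


def profile_to_dict(profile: AntioxidantProfile) -> dict:
    """Plain-dict form of a profile (suitable for YAML/JSON dumping)."""
    return profile.model_dump(by_alias=True, exclude_none=True)


def write_profile(
    profile: AntioxidantProfile,
    path: str | Path,
    format: Literal["json", "yaml", "csv-bundle"] | None = None,
) -> Path:
    """Serialize a profile; the inverse of :func:`read_profile`."""
    path = Path(path)
    if format is None:
        if path.suffix.lower() == ".json":
            format = "json"
        elif path.suffix.lower() in {".yaml", ".yml"}:
            format = "yaml"
        else:
            format = "csv-bundle"
    data = profile_to_dict(profile)
    if format == "json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    elif format == "yaml":
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        _write_csv_bundle(profile, path)
    return path


def _channel_to_row(ch: ReactionChannel) -> dict:
    row = {c: None for c in _CHANNEL_CSV_COLUMNS}
    row.update(
        mechanism=ch.mechanism,
        site=ch.site,
        radical=ch.radical,
        medium=ch.medium,
        species_state=ch.species_state,
        symmetry_number=ch.symmetry_number,
        activation_free_energy=ch.activation_free_energy,
        reaction_free_energy=ch.reaction_free_energy,
        barrierless=ch.barrierless,
        fixed_rate=ch.fixed_rate,
    )
    if isinstance(ch.tunneling, EckartParameters):
        row["eckart_forward"] = ch.tunneling.forward_barrier
        row["eckart_reverse"] = ch.tunneling.reverse_barrier
        row["eckart_frequency"] = ch.tunneling.imaginary_frequency
    elif ch.tunneling is not None:
        row["kappa"] = ch.tunneling
    if ch.marcus is not None:
        row["marcus_lambda"] = ch.marcus.reorganization_energy
        row["marcus_vertical_gap"] = ch.marcus.vertical_energy_gap
        row["marcus_dg0"] = ch.marcus.reaction_free_energy
    return row


def _row_to_channel_dict(row: dict) -> dict:
    def val(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    d: dict = {
        "mechanism": val("mechanism"),
        "site": val("site"),
        "radical": val("radical"),
        "medium": val("medium"),
        "species_state": val("species_state"),
    }
    if val("symmetry_number") is not None:
        d["symmetry_number"] = int(row["symmetry_number"])
    for key in ("activation_free_energy", "reaction_free_energy", "fixed_rate"):
        if val(key) is not None:
            d[key] = float(row[key])
    barrierless = val("barrierless")
    if barrierless is not None:
        d["barrierless"] = str(barrierless).strip().lower() in {"true", "1", "yes"}
    if val("eckart_frequency") is not None:
        d["tunneling"] = {
            "forward_barrier": float(row["eckart_forward"]),
            "reverse_barrier": float(row["eckart_reverse"]),
            "imaginary_frequency": float(row["eckart_frequency"]),
        }
    elif val("kappa") is not None:
        d["tunneling"] = float(row["kappa"])
    if val("marcus_lambda") is not None:
        d["marcus"] = {
            "reorganization_energy": float(row["marcus_lambda"]),
            "reaction_free_energy": float(row["marcus_dg0"]),
        }
        if val("marcus_vertical_gap") is not None:
            d["marcus"]["vertical_energy_gap"] = float(row["marcus_vertical_gap"])
    return d


def _write_csv_bundle(profile: AntioxidantProfile, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    fmt = lambda x: "" if x is None else repr(x) if isinstance(x, float) else x  # noqa: E731
    head = pd.DataFrame(
        [
            {
                "schema": profile.schema_version,
                "compound": profile.compound,
                "pka_values": ";".join(repr(p) for p in profile.acid_base.pka_values),
                "state_labels": ";".join(profile.acid_base.state_labels),
            }
        ]
    )
    head.to_csv(directory / "profile.csv", index=False)
    media = pd.DataFrame(
        [
            {
                "name": m.name,
                "is_aqueous": m.is_aqueous,
                "ph": fmt(m.ph),
                "viscosity": repr(m.viscosity),
                "diffusion_limits": json.dumps(m.diffusion_limit_override)
                if m.diffusion_limit_override
                else "",
            }
            for m in profile.media
        ]
    )
    media.to_csv(directory / "media.csv", index=False)
    species = pd.DataFrame(
        [
            {"label": s.label, "charge": s.charge, "mole_fraction": fmt(s.mole_fraction)}
            for s in profile.states
        ],
        columns=["label", "charge", "mole_fraction"],
    )
    species.to_csv(directory / "species.csv", index=False)
    channels = pd.DataFrame(
        [_channel_to_row(ch) for ch in profile.channels], columns=_CHANNEL_CSV_COLUMNS
    )
    channels.to_csv(directory / "channels.csv", index=False, float_format="%.17g")


def _read_csv_bundle(directory: Path) -> AntioxidantProfile:
    for name in ("profile.csv", "media.csv", "species.csv", "channels.csv"):
        if not (directory / name).exists():
            raise ProfileParseError(f"{directory}: CSV bundle is missing {name}")
    try:
        head = pd.read_csv(directory / "profile.csv").iloc[0]
        media_df = pd.read_csv(directory / "media.csv")
        species_df = pd.read_csv(directory / "species.csv")
        channels_df = pd.read_csv(directory / "channels.csv")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ProfileParseError(f"{directory}: {exc}") from exc

    def split_floats(cell) -> list[float]:
        if pd.isna(cell) or str(cell).strip() == "":
            return []
        return [float(x) for x in str(cell).split(";")]

    data: dict = {
        "schema": int(head["schema"]),
        "compound": str(head["compound"]),
        "acid_base": {
            "pka_values": split_floats(head.get("pka_values")),
            "state_labels": [s for s in str(head["state_labels"]).split(";") if s],
        },
        "media": [],
        "states": [],
        "channels": [],
    }
    for _, m in media_df.iterrows():
        entry: dict = {
            "name": str(m["name"]),
            "is_aqueous": str(m["is_aqueous"]).strip().lower() in {"true", "1", "yes"},
            "viscosity": float(m["viscosity"]),
        }
        if not pd.isna(m.get("ph")) and str(m.get("ph")).strip() != "":
            entry["ph"] = float(m["ph"])
        raw = m.get("diffusion_limits")
        if not pd.isna(raw) and str(raw).strip():
            entry["diffusion_limit_override"] = json.loads(str(raw))
        data["media"].append(entry)
    for _, s in species_df.iterrows():
        entry = {"label": str(s["label"]), "charge": int(s["charge"])}
        if not pd.isna(s.get("mole_fraction")):
            entry["mole_fraction"] = float(s["mole_fraction"])
        data["states"].append(entry)
    for _, row in channels_df.iterrows():
        data["channels"].append(_row_to_channel_dict(row.to_dict()))
    return _validate(data, str(directory))


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def _sig3(x: float | None) -> str:
    if x is None:
        return ""
    if x == 0:
        return "0"
    return f"{x:.3g}"


def write_report(
    results: Iterable,
    path: str | Path,
    format: Literal["csv", "markdown"] = "csv",
    title: str | None = None,
) -> Path:
    """Write a table of per-channel results (one compound/radical/medium group).

    ``results`` is a collection of :class:`radkin.aggregation.ChannelResult`;
    columns follow the layout of the per-medium kinetics tables: mechanism,
    site, state, dG_act, kappa, k_app, f, k_f, gamma, k_overall.  Numbers are
    formatted to 3 significant figures; weighted rates that are exactly zero
    are printed as ``~0``.
    """
    path = Path(path)
    results = list(results)
    k_overall = math.fsum(r.weighted_rate for r in results)
    rows = []
    for r in results:
        ch = r.channel
        kappa = None
        barrier = ch.activation_free_energy
        if r.evaluation is not None:
            kappa = r.evaluation.tunneling_used
            if r.evaluation.barrier_used is not None:
                barrier = r.evaluation.barrier_used
        if kappa is None and isinstance(ch.tunneling, (int, float)):
            kappa = float(ch.tunneling)
        rows.append(
            {
                "mechanism": ch.mechanism,
                "site": ch.site,
                "state": ch.species_state,
                "dG_act": _sig3(barrier),
                "kappa": _sig3(kappa),
                "k_app": _sig3(r.apparent_rate),
                "f": _sig3(r.mole_fraction),
                "k_f": "~0" if r.weighted_rate == 0.0 else _sig3(r.weighted_rate),
                "gamma": ""
                if r.branching_ratio is None
                else str(int(round(r.branching_ratio))),
                "k_overall": _sig3(k_overall),
            }
        )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    try:
        if format == "csv":
            frame.to_csv(path, index=False)
        else:
            lines = []
            if title:
                lines.append(f"### {title}")
                lines.append("")
            lines.append("| " + " | ".join(REPORT_COLUMNS) + " |")
            lines.append("| " + " | ".join("---" for _ in REPORT_COLUMNS) + " |")
            for row in rows:
                lines.append("| " + " | ".join(str(row[c]) for c in REPORT_COLUMNS) + " |")
            path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise ProfileError(f"cannot write report to {path}: {exc}") from exc
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a CSV report, mapping ``~0`` to 0.0."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("dG_act", "kappa", "k_app", "f", "k_f", "gamma", "k_overall"):
        frame[col] = [
            0.0 if v == "~0" else (float(v) if v != "" else math.nan)
            for v in frame[col]
        ]
    return frame
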