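"""Experiment configuration: factor levels, schedule, observation model, traits.

The default configuration encodes the factorial metacommunity design this
package emulates: six species compositions (five monocultures and the
five-species mixture) crossed with three main phosphorus-supply levels and
three N:P supply ratios, replicated three times, plus two extra phosphorus
levels run with the mixture only — 180 flasks organised into 60
metacommunities of three 50 mL patches.  The 31-day schedule includes four
partial medium exchanges and three dispersal events.

Configurations round-trip through YAML so that a run is fully described by
one structured text file (levels, volumes, schedule, seed, and per-species
geometry and growth parameters).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .species import GrowthParams, SpeciesTrait, default_traits

__all__ = [
    "ConfigurationError",
    "P_SUPPLY",
    "MIXTURE",
    "Schedule",
    "ObservationModel",
    "ExperimentConfig",
    "load_config",
    "save_config",
]


class ConfigurationError(ValueError):
    """Raised for invalid experiment configurations."""


#: Phosphorus supply (µmol P L⁻¹) by roman-numeral level name.
P_SUPPLY: dict[str, float] = {
    "I": 0.13,
    "II": 0.32,
    "III": 0.81,
    "IV": 2.02,
    "V": 5.02,
}

MIXTURE = "MIX"


@dataclass(frozen=True)
class Schedule:
    """Event schedule of the run (days are 1-based within the duration).

    ``exchange_events`` are (day, volume mL) pairs: that volume is removed
    from each patch and replaced with fresh medium at the patch's supply
    concentrations.  On each dispersal day, ``dispersal_volume_ml`` is drawn
    from each of the three patches of a metacommunity, pooled, mixed, and
    redistributed equally.
    """

    duration_days: int = 31
    exchange_events: tuple[tuple[int, float], ...] = (
        (3, 5.0),
        (6, 5.0),
        (10, 10.0),
        (17, 10.0),
    )
    dispersal_days: tuple[int, ...] = (13, 20, 27)
    dispersal_volume_ml: float = 2.5

    def __post_init__(self) -> None:
        for day, vol in self.exchange_events:
            if not 1 <= day <= self.duration_days:
                raise ConfigurationError(f"exchange day {day} outside duration")
            if vol <= 0:
                raise ConfigurationError("exchange volume must be > 0")
        for day in self.dispersal_days:
            if not 1 <= day <= self.duration_days:
                raise ConfigurationError(f"dispersal day {day} outside duration")
        if self.dispersal_volume_ml <= 0:
            raise ConfigurationError("dispersal volume must be > 0")


@dataclass(frozen=True)
class ObservationModel:
    """Utermöhl-style counting model.

    The effective examined volume of each sample is chosen so that the
    expected total cell count matches the target (a larger target for
    mixtures, matching the counting convention of at least 400 cells in
    monocultures and 1000 in mixtures); per-species counts are then Poisson.
    ``enabled=False`` returns noise-free observations.
    """

    target_count_mono: int = 400
    target_count_mix: int = 1000
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.target_count_mono < 1 or self.target_count_mix < 1:
            raise ConfigurationError("count targets must be >= 1")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one experiment run."""

    compositions: tuple[str, ...] = ("AN", "CL", "CY", "FR", "GY", MIXTURE)
    main_p_levels: tuple[str, ...] = ("I", "III", "V")
    extra_p_levels: tuple[str, ...] = ("II", "IV")
    extra_compositions: tuple[str, ...] = (MIXTURE,)
    np_ratios: tuple[float, ...] = (2.0, 16.0, 128.0)
    replicates: int = 3
    total_inoculum: float = 231_000.0  # µm³ mL⁻¹, substitutive design
    patch_volume_ml: float = 50.0
    p_supply: Mapping[str, float] = field(default_factory=lambda: dict(P_SUPPLY))
    schedule: Schedule = field(default_factory=Schedule)
    observation: ObservationModel = field(default_factory=ObservationModel)
    traits: Mapping[str, SpeciesTrait] = field(default_factory=default_traits)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name, levels in [
            ("compositions", self.compositions),
            ("np_ratios", self.np_ratios),
        ]:
            if len(levels) == 0:
                raise ConfigurationError(f"{name} must be non-empty")
            if len(set(levels)) != len(levels):
                raise ConfigurationError(f"duplicate labels in {name}: {levels}")
        if len(self.main_p_levels) == 0 and len(self.extra_p_levels) == 0:
            raise ConfigurationError("at least one phosphorus level is required")
        all_p = tuple(self.main_p_levels) + tuple(self.extra_p_levels)
        if len(set(all_p)) != len(all_p):
            raise ConfigurationError(f"duplicate phosphorus levels: {all_p}")
        for lvl in all_p:
            if lvl not in self.p_supply:
                raise ConfigurationError(f"no supply concentration for level {lvl!r}")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not self.total_inoculum > 0:
            raise ConfigurationError("total_inoculum must be > 0")
        if not self.patch_volume_ml > 0:
            raise ConfigurationError("patch_volume_ml must be > 0")
        for comp in self.compositions:
            if comp != MIXTURE and comp not in self.traits:
                raise ConfigurationError(f"composition {comp!r} has no species trait")
        for comp in self.extra_compositions:
            if comp not in self.compositions:
                raise ConfigurationError(
                    f"extra composition {comp!r} not among compositions"
                )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.traits)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "compositions": list(self.compositions),
            "main_p_levels": list(self.main_p_levels),
            "extra_p_levels": list(self.extra_p_levels),
            "extra_compositions": list(self.extra_compositions),
            "np_ratios": [float(x) for x in self.np_ratios],
            "replicates": self.replicates,
            "total_inoculum": self.total_inoculum,
            "patch_volume_ml": self.patch_volume_ml,
            "p_supply": {k: float(v) for k, v in self.p_supply.items()},
            "schedule": {
                "duration_days": self.schedule.duration_days,
                "exchange_events": [list(e) for e in self.schedule.exchange_events],
                "dispersal_days": list(self.schedule.dispersal_days),
                "dispersal_volume_ml": self.schedule.dispersal_volume_ml,
            },
            "observation": dataclasses.asdict(self.observation),
            "species": {
                code: {
                    "taxon_group": t.taxon_group,
                    "shape": t.shape,
                    "dimensions": dict(t.dimensions),
                    "mean_cell_biovolume": t.mean_cell_biovolume,
                    "growth": dataclasses.asdict(t.growth),
                }
                for code, t in self.traits.items()
            },
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        kwargs: dict = {}
        simple = (
            "replicates",
            "total_inoculum",
            "patch_volume_ml",
            "seed",
        )
        for key in simple:
            if key in d:
                kwargs[key] = d[key]
        for key in (
            "compositions",
            "main_p_levels",
            "extra_p_levels",
            "extra_compositions",
            "np_ratios",
        ):
            if key in d:
                kwargs[key] = tuple(d[key])
        if "p_supply" in d:
            kwargs["p_supply"] = {str(k): float(v) for k, v in d["p_supply"].items()}
        if "schedule" in d:
            s = d["schedule"]
            kwargs["schedule"] = Schedule(
                duration_days=s.get("duration_days", 31),
                exchange_events=tuple(
                    (int(day), float(vol)) for day, vol in s.get("exchange_events", ())
                ),
                dispersal_days=tuple(int(x) for x in s.get("dispersal_days", ())),
                dispersal_volume_ml=float(s.get("dispersal_volume_ml", 2.5)),
            )
        if "observation" in d:
            kwargs["observation"] = ObservationModel(**d["observation"])
        if "species" in d:
            traits = {}
            for code, spec in d["species"].items():
                traits[code] = SpeciesTrait(
                    name=code,
                    taxon_group=spec.get("taxon_group", ""),
                    shape=spec["shape"],
                    dimensions={k: float(v) for k, v in spec["dimensions"].items()},
                    mean_cell_biovolume=float(spec.get("mean_cell_biovolume", 0.0)),
                    growth=GrowthParams(**spec["growth"]),
                )
            kwargs["traits"] = traits
        try:
            return cls(**kwargs)
        except TypeError as exc:  # unknown keys etc.
            raise ConfigurationError(str(exc)) from exc

    def hash(self) -> str:
        """Stable SHA-256 hash of the canonical configuration dict."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return ExperimentConfig()
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config file {path} is not a mapping")
    return ExperimentConfig.from_dict(data)


def save_config(config: ExperimentConfig, path) -> None:
    """Write a configuration to YAML (round-trips with :func:`load_config`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
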