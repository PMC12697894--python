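"""Run configuration: scenario setup, defaults, fixture scaling and YAML I/O.

All defaults reproduce the published study conditions; ``make_fixture``
produces density-preserving scaled arenas (area and every colony capacity
scaled together) so per-capita dynamics are unchanged while runs stay fast.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

import yaml

from .colonies import GrowthParams
from .genetics import DriveConfig, DriveVariant
from .spatial import Arena, CompetitionParams

__all__ = [
    "Scenario",
    "ScenarioConfig",
    "RunConfig",
    "make_fixture",
]


class Scenario(str, enum.Enum):
    MONOGYNE_ONLY = "monogyne_only"
    POLYGYNE_ONLY = "polygyne_only"
    MIXED = "mixed"
    NATIVE_COEXIST = "native_coexist"
    INVASION = "invasion"


# pure-polygyne full-arena capacity equivalent (30 941 per half arena)
_POLYGYNE_FULL = 61_882


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario layout, releases and mating parameters.

    ``polygyne_male_rate`` down-weights polygyne colonies in mate selection
    (they produce fewer males); its default exactly offsets their 1.2x
    biomass so they are not selected at a higher rate than monogyne.
    """

    scenario: Scenario = Scenario.MIXED
    years: int = 100
    init_monogyne: int = 50_000
    init_polygyne: int = 30_941
    init_native: int = 0
    release_fraction: float = 0.15
    release_years: int = 6
    release_sb_fraction: float = 0.5
    polygyne_male_rate: float = 0.837352526
    mate_attempts: int = 10
    mate_radius_factor: float = 2.0
    mate_fallback_k: int = 50
    replacement_attempts: int = 10
    avg_dispersal: float = 100.0
    polygyne_dispersal_fraction: float = 0.5
    invasion_fire_fraction: float = 0.4
    invasion_trigger_slice: int = 7
    invasion_trigger_fraction: float = 0.5

    def __post_init__(self) -> None:
        if isinstance(self.scenario, str) and not isinstance(self.scenario, Scenario):
            object.__setattr__(self, "scenario", Scenario(self.scenario))
        for name in ("init_monogyne", "init_polygyne", "init_native"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("release_fraction", "release_sb_fraction",
                     "polygyne_dispersal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _scenario_defaults(scenario: Scenario) -> dict[str, Any]:
    if scenario == Scenario.MONOGYNE_ONLY:
        return {"init_monogyne": 100_000, "init_polygyne": 0, "init_native": 0}
    if scenario == Scenario.POLYGYNE_ONLY:
        return {"init_monogyne": 0, "init_polygyne": _POLYGYNE_FULL, "init_native": 0}
    if scenario == Scenario.MIXED:
        return {"init_monogyne": 50_000, "init_polygyne": 30_941, "init_native": 0}
    if scenario == Scenario.NATIVE_COEXIST:
        return {"init_monogyne": 50_000, "init_polygyne": 30_941, "init_native": 50_000}
    if scenario == Scenario.INVASION:
        # fire ants hold the left 40% (polygyne in its left half), natives the rest
        return {
            "init_monogyne": 20_000,
            "init_polygyne": round(0.2 * _POLYGYNE_FULL),
            "init_native": 60_000,
            "avg_dispersal": 138.75,
        }
    raise ValueError(scenario)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one simulation run."""

    drive: DriveConfig = field(default_factory=DriveConfig)
    growth: GrowthParams = field(default_factory=GrowthParams)
    competition: CompetitionParams = field(default_factory=CompetitionParams)
    arena: Arena = field(default_factory=Arena)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    replicates: int = 1
    seed: int = 1

    @classmethod
    def for_scenario(cls, scenario: Scenario | str, **overrides) -> "RunConfig":
        """Default configuration for a named scenario.

        Keyword overrides are routed to the sub-configuration that owns the
        field (e.g. ``conversion_rate`` to the drive, ``years`` to the
        scenario block).
        """
        scenario = Scenario(scenario)
        scen_kwargs = dict(_scenario_defaults(scenario), scenario=scenario)
        comp_kwargs: dict[str, Any] = {}
        if scenario == Scenario.NATIVE_COEXIST:
            comp_kwargs = {"n_monogyne": 50_000.0, "n_polygyne": 30_941.0,
                           "n_native": 50_000.0}
        parts = {
            "drive": (DriveConfig, {}),
            "growth": (GrowthParams, {}),
            "competition": (CompetitionParams, comp_kwargs),
            "scenario": (ScenarioConfig, scen_kwargs),
            "arena": (Arena, {}),
        }
        top: dict[str, Any] = {}
        for key, val in overrides.items():
            routed = False
            for name, (klass, kwargs) in parts.items():
                if key in {f.name for f in dataclasses.fields(klass)}:
                    kwargs[key] = val
                    routed = True
                    break
            if not routed:
                if key in {f.name for f in dataclasses.fields(cls)}:
                    top[key] = val
                else:
                    raise TypeError(f"unknown configuration field {key!r}")
        return cls(
            drive=DriveConfig(**parts["drive"][1]),
            growth=GrowthParams(**parts["growth"][1]),
            competition=CompetitionParams(**parts["competition"][1]),
            arena=Arena(**parts["arena"][1]),
            scenario=ScenarioConfig(**parts["scenario"][1]),
            **top,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: clean(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, enum.Enum):
                return obj.value
            return obj

        return clean(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(
            drive=DriveConfig(**data.get("drive", {})),
            growth=GrowthParams(**data.get("growth", {})),
            competition=CompetitionParams(**data.get("competition", {})),
            arena=Arena(**data.get("arena", {})),
            scenario=ScenarioConfig(**data.get("scenario", {})),
            replicates=int(data.get("replicates", 1)),
            seed=int(data.get("seed", 1)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def make_fixture(config: RunConfig, scale: float) -> RunConfig:
    """Density-preserving scaled fixture.

    Scales the arena *area* and every colony capacity / initial count by
    ``scale``, leaving distances (dispersal, competition radii, mate search)
    untouched, so competition ratios and per-capita dynamics are unchanged
    while runs are ~1/scale faster.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    if scale == 1.0:
        return config
    arena = Arena(side=config.arena.side * math.sqrt(scale))
    comp = replace(
        config.competition,
        n_monogyne=config.competition.n_monogyne * scale,
        n_polygyne=config.competition.n_polygyne * scale,
        n_native=config.competition.n_native * scale,
    )
    scen = replace(
        config.scenario,
        init_monogyne=round(config.scenario.init_monogyne * scale),
        init_polygyne=round(config.scenario.init_polygyne * scale),
        init_native=round(config.scenario.init_native * scale),
    )
    return replace(config, arena=arena, competition=comp, scenario=scen)
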