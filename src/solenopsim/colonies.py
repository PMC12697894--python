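"""Colony state, growth curves, queen production and age-dependent mortality.

Every colony is represented by a single queen genotype plus the stored
genotype of her (haploid) mate.  Colony size follows a logistic growth
curve in colony age; polygyne colonies hold roughly twice as many (smaller)
workers but are assumed to produce the same number of new queens as a
monogyne colony of the same age.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genetics import DriveConfig, Genome, SocialForm, fecundity_multiplier

__all__ = [
    "Species",
    "GrowthParams",
    "Colony",
    "colony_size",
    "monogyne_equivalent_size",
    "queen_production_mean",
    "expected_queen_count",
    "age_survival",
    "ReplacementOutcome",
    "polygyne_replacement",
]


class Species(enum.IntEnum):
    FIRE_ANT = 0
    NATIVE = 1


@dataclass(frozen=True)
class GrowthParams:
    """Growth-curve, queen-production and lifespan parameters.

    ``offspring_calibration`` is the factor applied to queen production so
    that spatial simulations hold the intended carrying capacity despite the
    over-dispersed colony pattern density-dependent mortality produces.
    """

    s_max_monogyne: float = 170_000.0
    s_max_polygyne: float = 340_000.0
    shape: float = 66.0          # logistic shape parameter
    rate: float = 1.3            # logistic rate, per year
    maintenance: float = 10_000.0   # workers needed before any queen is produced
    workers_per_queen: float = 10_800.0
    offspring_calibration: float = 0.95
    queen_replacement_prob: float = 0.5
    replacement_fail_death: float = 0.8
    max_age_monogyne: int = 7
    age6_death: float = 0.5
    age6: int = 6
    max_age_polygyne: int = 70


@dataclass
class Colony:
    """A single simulation agent (used by the scalar API and small tests;
    the spatial engine stores the same fields in flat arrays)."""

    id: int
    position: tuple[float, float]
    age: int
    form: SocialForm
    species: Species
    queen: Genome
    mate: Optional[Genome] = None
    alive: bool = True

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("colony age must be non-negative")
        if self.species == Species.NATIVE and self.form != SocialForm.MONOGYNE:
            raise ValueError("native colonies are monogyne-form")


def _logistic(t: float, s_max: float, p: GrowthParams) -> float:
    return s_max / (1.0 + p.shape * math.exp(-p.rate * t))


def colony_size(t, form: SocialForm, species: Species = Species.FIRE_ANT,
                params: GrowthParams = GrowthParams()):
    """Number of workers at colony age ``t`` (years); accepts arrays."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("colony age must be non-negative")
    s_max = (
        params.s_max_polygyne
        if (species == Species.FIRE_ANT and form == SocialForm.POLYGYNE)
        else params.s_max_monogyne
    )
    out = s_max / (1.0 + params.shape * np.exp(-params.rate * t))
    return float(out) if out.ndim == 0 else out


def monogyne_equivalent_size(t, params: GrowthParams = GrowthParams()):
    """Monogyne-curve size at age ``t`` — the competition- and
    queen-production-relevant size for every colony regardless of form."""
    t = np.asarray(t, dtype=float)
    out = params.s_max_monogyne / (1.0 + params.shape * np.exp(-params.rate * t))
    return float(out) if out.ndim == 0 else out


def queen_production_mean(age, fecundity: float = 1.0,
                          params: GrowthParams = GrowthParams()):
    """Poisson mean of new-queen production for a colony of the given age.

    Both social forms use the monogyne-equivalent size (polygyne colonies
    are bigger but their workers and new queens are smaller); the polygyne
    greenbeard cull of non-Sb daughters is applied downstream.
    """
    s = monogyne_equivalent_size(age, params)
    base = np.maximum(0.0, (s - params.maintenance) / params.workers_per_queen)
    return base * fecundity * params.offspring_calibration


def expected_queen_count(colony: Colony, cfg: DriveConfig,
                         params: GrowthParams, rng: np.random.Generator) -> int:
    """Draw the number of new queens a colony produces this year."""
    if colony.age < 2 or colony.mate is None:
        return 0
    fec = fecundity_multiplier(colony.queen, cfg)
    if fec <= 0.0:
        return 0
    return int(rng.poisson(queen_production_mean(colony.age, fec, params)))


def age_survival(age: int, form: SocialForm, species: Species,
                 params: GrowthParams, rng: np.random.Generator) -> bool:
    """Age-related survival, applied once per year after density survival.

    Monogyne and native colonies die with probability ``age6_death`` in the
    year they are age 6 and never survive past age 7; polygyne colonies are
    hard-capped at 70 years (their turnover is otherwise governed by
    representative-queen replacement failure).
    """
    if species == Species.FIRE_ANT and form == SocialForm.POLYGYNE:
        return age < params.max_age_polygyne
    if age >= params.max_age_monogyne:
        return False
    if age == params.age6:
        return bool(rng.random() >= params.age6_death)
    return True


class ReplacementOutcome(enum.Enum):
    REPLACED = "replaced"
    RETAINED = "retained"
    DIED = "died"


def polygyne_replacement(candidate_available: bool, params: GrowthParams,
                         rng: np.random.Generator) -> ReplacementOutcome:
    """Yearly representative-queen replacement of a polygyne colony.

    With probability ``queen_replacement_prob`` the colony attempts to
    install a newly mated queen genotype.  An attempt succeeds whenever a
    viable candidate is available; an attempt that finds none kills the
    colony with probability ``replacement_fail_death``.  Years without an
    attempt simply retain the previous queen genotype — in an intact
    population replacement failure is therefore rare, while under drive
    suppression the scarcity of fertile new queens shortens colony lifespan.
    """
    if rng.random() >= params.queen_replacement_prob:
        return ReplacementOutcome.RETAINED
    if candidate_available:
        return ReplacementOutcome.REPLACED
    if rng.random() < params.replacement_fail_death:
        return ReplacementOutcome.DIED
    return ReplacementOutcome.RETAINED
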