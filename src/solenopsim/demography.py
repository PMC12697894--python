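"""Equilibrium life tables, stable age structure and generation times.

Everything here is evaluated at competition ratio R = 1, the definition of
demographic equilibrium: a newly founded monogyne colony survives
establishment with probability 0.1, then passes through the age-specific
density survivals of the logistic growth curve, the 50% age-6 cull and the
hard age-7 cap.  The yearly cycle reproduces *before* mortality, so the
survivorship that weights age-t reproduction is survival through the end
of age t-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colonies import GrowthParams, monogyne_equivalent_size, queen_production_mean
from .spatial import CompetitionParams, age0_survival, density_survival

__all__ = [
    "MonogyneLifeTable",
    "monogyne_life_table",
    "equilibrium_age_distribution",
    "monogyne_generation_time",
    "polygyne_generation_time",
]


@dataclass(frozen=True)
class MonogyneLifeTable:
    """Life table of a monogyne colony at R = 1.

    ages
        Reproductive ages (2..7).
    survivorship
        l_t: probability a newly produced queen is alive (as a colony) at
        the reproduction step of age t.
    fecundity
        m_t: mean queens produced at age t (including the 0.95 calibration).
    """

    ages: np.ndarray
    survivorship: np.ndarray
    fecundity: np.ndarray

    @property
    def net_reproduction(self) -> float:
        """R0, expected lifetime queen production of a newly produced queen."""
        return float(np.sum(self.survivorship * self.fecundity))

    @property
    def generation_time(self) -> float:
        """Mean mother age at daughter production, weighted by l_t * m_t."""
        w = self.survivorship * self.fecundity
        return float(np.sum(self.ages * w) / np.sum(w))


def _yearly_survivals(growth: GrowthParams, comp: CompetitionParams, R: float = 1.0) -> np.ndarray:
    """Density survival through ages 1..max-1 at competition ratio R."""
    ages = np.arange(1, growth.max_age_monogyne, dtype=float)
    return density_survival(monogyne_equivalent_size(ages, growth), R,
                            comp.survival_ceiling_monogyne, comp)


def monogyne_life_table(growth: GrowthParams = GrowthParams(),
                        comp: CompetitionParams = CompetitionParams(),
                        R: float = 1.0) -> MonogyneLifeTable:
    s = _yearly_survivals(growth, comp, R)  # s[t-1] = survival through age t
    ages = np.arange(2, growth.max_age_monogyne + 1)
    l0 = age0_survival(R, comp.low_density_growth, comp.age0_base)
    surv = np.empty(len(ages))
    acc = l0
    for i, t in enumerate(ages):
        acc *= s[t - 2]                       # survive through age t-1
        if t - 1 == growth.age6:
            acc *= 1.0 - growth.age6_death    # age-6 cull precedes age-7 breeding
        surv[i] = acc
    fec = queen_production_mean(ages, 1.0, growth)
    return MonogyneLifeTable(ages=ages, survivorship=surv, fecundity=fec)


def equilibrium_age_distribution(growth: GrowthParams = GrowthParams(),
                                 comp: CompetitionParams = CompetitionParams()) -> np.ndarray:
    """Stationary proportions p_t of established colonies over ages 2..7.

    Proportional to the R = 1 survivorship schedule; used to weight the
    age classes in the expected-competition normalization.
    """
    lt = monogyne_life_table(growth, comp)
    return lt.survivorship / lt.survivorship.sum()


def monogyne_generation_time(growth: GrowthParams = GrowthParams(),
                             comp: CompetitionParams = CompetitionParams()) -> float:
    """Mean mother age of monogyne colonies at equilibrium (years)."""
    return monogyne_life_table(growth, comp).generation_time


def polygyne_generation_time(replacement_prob: float | None = None,
                             growth: GrowthParams = GrowthParams()) -> float:
    """Effective generation time of the polygyne representative genotype.

    A representative genotype starts as a newly mated queen and produces
    daughters from the following year on, persisting each year with
    probability (1 - replacement rate); the mean genotype age at daughter
    production is then about 1/p (2 years at the default 50% replacement).
    """
    p = growth.queen_replacement_prob if replacement_prob is None else replacement_prob
    if not 0.0 < p <= 1.0:
        raise ValueError("replacement probability must lie in (0, 1]")
    ages = np.arange(1, growth.max_age_polygyne + 1, dtype=float)
    w = (1.0 - p) ** (ages - 1.0)
    return float(np.sum(ages * w) / np.sum(w))
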