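"""Arena geometry, dispersal, the competition kernel and density survival.

Competition is pairwise and local: a source colony exerts pressure
proportional to its (monogyne-equivalent) size within a radius derived
from its territory area, declining linearly with distance.  Each focal
colony's *competition ratio* R is its summed incoming pressure divided by
the pressure expected in an equilibrium population at carrying capacity;
R drives both new-colony establishment and adult density survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .colonies import GrowthParams, Species, monogyne_equivalent_size
from .genetics import SocialForm

__all__ = [
    "Arena",
    "CompetitionParams",
    "dispersal_sigma",
    "dispersal_draw",
    "competition_radius",
    "pairwise_competition",
    "actual_competition",
    "actual_competition_bruteforce",
    "expected_competition",
    "density_survival",
    "age0_survival",
    "nearest_neighbor_index",
]


@dataclass(frozen=True)
class Arena:
    """Square arena; positions outside are redrawn, never clipped."""

    side: float = 1850.0

    @property
    def area(self) -> float:
        return self.side * self.side

    def contains(self, x, y):
        return (x >= 0.0) & (x <= self.side) & (y >= 0.0) & (y <= self.side)


@dataclass(frozen=True)
class CompetitionParams:
    """Competition kernel, survival and capacity parameters.

    ``survival_rate_constant`` scales colony size inside the exponential of
    the density-survival curve; it is exposed so the curve can be
    re-calibrated against the carrying-capacity check if needed.
    """

    n_monogyne: float = 100_000.0       # monogyne-only equilibrium capacity
    n_polygyne: float = 61_882.0        # polygyne full-arena capacity equivalent
    n_native: float = 100_000.0
    territory_mature: float = 100.0     # m^2 for a mature colony
    radius_multiplier: float = 2.0      # doubled so overlapping territories compete
    polygyne_exert_factor: float = 1.2  # 2x workers at 0.6 relative mass
    polygyne_pair_coefficient: float = 1.0 / 1.2
    interspecies_factor: float = 0.5
    low_density_growth: float = 6.0
    survival_ceiling_monogyne: float = 0.95
    survival_ceiling_polygyne: float = 0.90
    survival_amplitude: float = 0.6714
    survival_rate_constant: float = 2.2221 / 100_000.0
    age0_base: float = 0.1


def dispersal_sigma(average_dispersal: float) -> float:
    """Per-axis Gaussian sigma giving the requested mean Euclidean displacement.

    Displacements are independent per-axis normals, so the distance is
    Rayleigh with mean sigma*sqrt(pi/2); invert for sigma.
    """
    return average_dispersal * math.sqrt(2.0 / math.pi)


def dispersal_draw(origin: tuple[float, float], average_dispersal: float,
                   arena: Arena, rng: np.random.Generator) -> tuple[float, float]:
    """New-queen settlement position; the full displacement is redrawn until
    it lands inside the arena."""
    sigma = dispersal_sigma(average_dispersal)
    x0, y0 = origin
    if sigma == 0.0:
        return (x0, y0)
    while True:
        x = x0 + sigma * rng.standard_normal()
        y = y0 + sigma * rng.standard_normal()
        if arena.contains(x, y):
            return (x, y)


def dispersal_draw_batch(x0: np.ndarray, y0: np.ndarray, sigma: np.ndarray,
                         arena: Arena, rng: np.random.Generator):
    """Vectorized dispersal with redraw-if-outside."""
    n = x0.shape[0]
    x = x0 + sigma * rng.standard_normal(n)
    y = y0 + sigma * rng.standard_normal(n)
    bad = ~arena.contains(x, y)
    while np.any(bad):
        m = int(bad.sum())
        x[bad] = x0[bad] + sigma[bad] * rng.standard_normal(m)
        y[bad] = y0[bad] + sigma[bad] * rng.standard_normal(m)
        bad = ~arena.contains(x, y)
    return x, y


def competition_radius(t, params: CompetitionParams = CompetitionParams(),
                       growth: GrowthParams = GrowthParams()):
    """Interaction radius of an age-``t`` source colony (metres).

    Territory area scales with monogyne-equivalent biomass relative to a
    mature colony (both forms hold the same territory at the same age); the
    circle radius is then doubled so overlapping territories interact.
    """
    t = np.asarray(t, dtype=float)
    area = params.territory_mature * monogyne_equivalent_size(t, growth) / growth.s_max_monogyne
    out = params.radius_multiplier * np.sqrt(area / math.pi)
    return float(out) if out.ndim == 0 else out


def _source_strength(age, form, params: CompetitionParams, growth: GrowthParams):
    s = monogyne_equivalent_size(age, growth)
    return np.where(form == int(SocialForm.POLYGYNE), s * params.polygyne_exert_factor, s)


def pairwise_competition(source_age: int, source_form: SocialForm, source_species: Species,
                         focal_form: SocialForm, focal_species: Species, d: float,
                         params: CompetitionParams = CompetitionParams(),
                         growth: GrowthParams = GrowthParams(),
                         native_on_fire_factor: Optional[float] = None) -> float:
    """Competition exerted by one source on one focal colony at distance d.

    The kernel declines linearly to zero at the source's radius.  Polygyne
    sources exert 20% more (doubled workers at 0.6 mass), polygyne pairs
    discount each other by 1/1.2 (they do not fight), and cross-species
    pressure is scaled by the interspecies factor (asymmetrically in the
    invasion scenario, where only native-on-fire pressure is reduced).
    """
    r = competition_radius(source_age, params, growth)
    if d >= r:
        return 0.0
    val = _source_strength(source_age, int(source_form), params, growth) * (1.0 - d / r)
    if source_form == SocialForm.POLYGYNE and focal_form == SocialForm.POLYGYNE:
        val *= params.polygyne_pair_coefficient
    if source_species != focal_species:
        if native_on_fire_factor is not None:
            if source_species == Species.NATIVE and focal_species == Species.FIRE_ANT:
                val *= native_on_fire_factor
        else:
            val *= params.interspecies_factor
    return float(val)


def actual_competition(x, y, age, form, species,
                       params: CompetitionParams = CompetitionParams(),
                       growth: GrowthParams = GrowthParams(),
                       native_on_fire_factor: Optional[float] = None) -> np.ndarray:
    """Summed incoming competition for every colony (spatially indexed).

    Sources are colonies of age >= 1 (age-0 colonies are too small to exert
    pressure); every colony, age 0 included, receives.  Results match the
    brute-force all-pairs sum exactly.
    """
    n = x.shape[0]
    out = np.zeros(n)
    if n < 2 or not np.any(age >= 1):
        return out
    # age-indexed lookup tables keep the per-pair arithmetic cheap
    amax = int(np.max(age))
    ages_tab = np.arange(amax + 1, dtype=float)
    s_tab = monogyne_equivalent_size(ages_tab, growth)
    r_tab = competition_radius(ages_tab, params, growth)
    rmax = float(r_tab[int(np.max(age[age >= 1]))])

    tree = cKDTree(np.column_stack([x, y]))
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if pairs.size == 0:
        return out
    d = np.hypot(x[pairs[:, 0]] - x[pairs[:, 1]], y[pairs[:, 0]] - y[pairs[:, 1]])
    poly = np.asarray(form) == int(SocialForm.POLYGYNE)
    native = np.asarray(species) == int(Species.NATIVE)

    for src, foc in ((pairs[:, 0], pairs[:, 1]), (pairs[:, 1], pairs[:, 0])):
        m = age[src] >= 1
        if not np.any(m):
            continue
        srcm, focm, dm = src[m], foc[m], d[m]
        r = r_tab[age[srcm]]
        inside = dm < r
        srcm, focm, dm, r = srcm[inside], focm[inside], dm[inside], r[inside]
        val = s_tab[age[srcm]] * (1.0 - dm / r)
        sp, fp = poly[srcm], poly[focm]
        val[sp] *= params.polygyne_exert_factor
        val[sp & fp] *= params.polygyne_pair_coefficient
        cross = native[srcm] != native[focm]
        if native_on_fire_factor is not None:
            val[cross & native[srcm]] *= native_on_fire_factor
        else:
            val[cross] *= params.interspecies_factor
        out += np.bincount(focm, weights=val, minlength=n)
    return out


def actual_competition_bruteforce(x, y, age, form, species,
                                  params: CompetitionParams = CompetitionParams(),
                                  growth: GrowthParams = GrowthParams(),
                                  native_on_fire_factor: Optional[float] = None) -> np.ndarray:
    """All-pairs reference implementation (oracle for the indexed version)."""
    n = x.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j or age[j] < 1:
                continue
            d = math.hypot(x[j] - x[i], y[j] - y[i])
            out[i] += pairwise_competition(
                int(age[j]), SocialForm(int(form[j])), Species(int(species[j])),
                SocialForm(int(form[i])), Species(int(species[i])), d,
                params, growth, native_on_fire_factor)
    return out


def expected_competition(capacity: float, arena: Arena,
                         params: CompetitionParams = CompetitionParams(),
                         growth: GrowthParams = GrowthParams(),
                         exert_factor: float = 1.0,
                         age_distribution: Optional[np.ndarray] = None) -> float:
    """Expected competition from one population at its equilibrium capacity.

    Sums over the equilibrium age classes t = 2..7: source size x density of
    that age class x the kernel integral pi*r_t^2/3 (the 1/3 is the average
    of the linear decline over the disc).  Cross-species or polygyne terms
    are obtained by scaling ``capacity``/``exert_factor`` and summing.
    """
    if age_distribution is None:
        from .demography import equilibrium_age_distribution

        age_distribution = equilibrium_age_distribution(growth, params)
    ages = np.arange(2, 2 + len(age_distribution), dtype=float)
    s = monogyne_equivalent_size(ages, growth) * exert_factor
    r = competition_radius(ages, params, growth)
    dens = capacity * age_distribution / arena.area
    return float(np.sum(s * dens * math.pi * r**2 / 3.0))


def density_survival(size, R, ceiling: float = 0.95,
                     params: CompetitionParams = CompetitionParams()):
    """Density-dependent yearly survival of an established colony.

    ``size`` is the monogyne-equivalent colony size, ``R`` the competition
    ratio.  Survival rises toward the ceiling (0.95 monogyne/native, 0.90
    polygyne) for large colonies under light competition.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0.0):
        raise ValueError("competition ratio must be positive")
    out = ceiling - params.survival_amplitude * np.exp(
        -params.survival_rate_constant * np.asarray(size, dtype=float) / R
    )
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def age0_survival(R, g: float = 6.0, base: float = 0.1):
    """Establishment survival of a newly founded colony.

    Equals ``base * g`` when competition vanishes and ``base`` at R = 1, so
    ``g`` is the low-density growth rate of the population.
    """
    if g <= 1.0:
        raise ValueError("low-density growth rate must exceed 1")
    R = np.asarray(R, dtype=float)
    if np.any(R < 0.0):
        raise ValueError("competition ratio must be non-negative")
    out = np.clip(base * g / ((g - 1.0) * R + 1.0), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def nearest_neighbor_index(positions: np.ndarray, area: float) -> float:
    """Clark-Evans nearest-neighbor index of a point pattern.

    Ratio of the mean nearest-neighbor distance to the value 0.5/sqrt(n/area)
    expected under complete spatial randomness: ~1 for random patterns, <1
    for clustered, >1 for dispersed ones.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("nearest-neighbor index requires at least two points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    mean_nn = float(d[:, 1].mean())
    expected = 0.5 / math.sqrt(pts.shape[0] / area)
    return mean_nn / expected
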