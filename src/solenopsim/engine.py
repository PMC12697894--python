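"""Yearly-cycle spatial simulation of fire-ant colonies under a gene drive.

Each simulated year executes, in order: age increment; reproduction by
established colonies (germline gametes, embryo resistance, viability /
sterility / greenbeard filters, dispersal); polygyne representative-queen
replacement; mating of age-1 queens (including released drive males);
competition-ratio computation; survival (establishment survival for age-0
colonies, density survival plus age-related death for older ones); and
metrics recording.  Colony state lives in flat numpy arrays; all genetic
sampling goes through the vectorized kernels in :mod:`.genetics`, and
mate selection is processed in batched attempt rounds whose candidate
sampling is exactly biomass-and-fitness weighted within each queen's
search radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import genetics as gn
from .colonies import GrowthParams, Species, monogyne_equivalent_size, queen_production_mean
from .config import RunConfig, Scenario
from .demography import equilibrium_age_distribution
from .genetics import DriveConfig, DriveVariant, SocialForm
from .metrics import (
    MASS_FACTOR_MONOGYNE,
    MASS_FACTOR_POLYGYNE,
    YearRecord,
    allele_frequencies,
    biomass_by_group,
    records_to_frame,
    slice_biomass,
)
from .spatial import (
    actual_competition,
    age0_survival,
    dispersal_draw_batch,
    dispersal_sigma,
    expected_competition,
    nearest_neighbor_index,
)

__all__ = ["ColonyState", "Simulation", "RunResult", "run_replicates"]

_MONO = int(SocialForm.MONOGYNE)
_POLY = int(SocialForm.POLYGYNE)
_FIRE = int(Species.FIRE_ANT)
_NATIVE = int(Species.NATIVE)

_GENOME_COLS = ("qf1", "qf2", "qs1", "qs2", "qd1", "qd2", "mf", "ms", "md")
_COLS = ("x", "y", "age", "form", "species") + _GENOME_COLS + ("mated",)


@dataclass
class ColonyState:
    """Flat arrays, one row per living colony."""

    x: np.ndarray
    y: np.ndarray
    age: np.ndarray
    form: np.ndarray
    species: np.ndarray
    qf1: np.ndarray
    qf2: np.ndarray
    qs1: np.ndarray
    qs2: np.ndarray
    qd1: np.ndarray
    qd2: np.ndarray
    mf: np.ndarray
    ms: np.ndarray
    md: np.ndarray
    mated: np.ndarray

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @classmethod
    def empty(cls) -> "ColonyState":
        return cls(
            x=np.empty(0), y=np.empty(0),
            age=np.empty(0, dtype=np.int32),
            form=np.empty(0, dtype=np.int8),
            species=np.empty(0, dtype=np.int8),
            **{c: np.empty(0, dtype=np.int8) for c in _GENOME_COLS},
            mated=np.empty(0, dtype=bool),
        )

    def select(self, idx) -> "ColonyState":
        return ColonyState(**{c: getattr(self, c)[idx] for c in _COLS})

    @staticmethod
    def concatenate(parts: list["ColonyState"]) -> "ColonyState":
        parts = [p for p in parts if p.n > 0] or [ColonyState.empty()]
        return ColonyState(**{
            c: np.concatenate([getattr(p, c) for p in parts]) for c in _COLS})


class _MatePool:
    """Father-colony candidates of one species for one year's matings."""

    __slots__ = ("idx", "w", "cum", "total", "tree", "px", "py")

    def __init__(self, idx, w, px, py):
        self.idx = idx
        self.w = w
        self.px = px
        self.py = py
        self.cum = np.cumsum(w) if idx.size else np.empty(0)
        self.total = float(self.cum[-1]) if idx.size else 0.0
        self.tree = cKDTree(np.column_stack([px, py])) if idx.size else None


@dataclass
class RunResult:
    """Outcome of one replicate: yearly records plus termination info."""

    records: pd.DataFrame
    termination: str
    termination_year: int
    release_start: Optional[int]
    config: RunConfig
    seed: int

    @property
    def initial_fire_biomass(self) -> float:
        return float(self.records["biomass_fire"].iloc[0])

    def biomass_reduction(self, year: Optional[int] = None) -> float:
        """Fractional fire-biomass reduction relative to year 0.

        If the requested year lies beyond the (possibly early-terminated)
        record, the last available year is used — after elimination the
        reduction is already 100%.
        """
        series = self.records.set_index("year")["biomass_fire"]
        value = series.iloc[-1] if year is None or year not in series.index else series.loc[year]
        return 1.0 - float(value) / self.initial_fire_biomass

    def years_to_reduction(self, fraction: float = 0.9) -> Optional[int]:
        """Years after first release until fire biomass first drops below
        (1 - fraction) of its initial value; None if never reached."""
        if self.release_start is None:
            return None
        threshold = (1.0 - fraction) * self.initial_fire_biomass
        hit = self.records[(self.records["year"] >= self.release_start)
                           & (self.records["biomass_fire"] <= threshold)]
        if hit.empty:
            return None
        return int(hit["year"].iloc[0]) - self.release_start


class Simulation:
    """One replicate of the spatial colony model."""

    def __init__(self, config: RunConfig, seed: Optional[int] = None):
        self.config = config
        self.cfg = config.drive
        self.growth = config.growth
        self.comp = config.competition
        self.arena = config.arena
        self.scen = config.scenario
        self.seed = config.seed if seed is None else seed
        self.rng = np.random.default_rng(np.random.SeedSequence(self.seed))

        self._sigma_mono = dispersal_sigma(self.scen.avg_dispersal)
        self._sigma_poly = dispersal_sigma(
            self.scen.avg_dispersal * self.scen.polygyne_dispersal_fraction)
        self._p_ages = equilibrium_age_distribution(self.growth, self.comp)
        self._setup_expected_competition()
        ages = np.arange(self.growth.max_age_polygyne + 2, dtype=float)
        self._size_tab = monogyne_equivalent_size(ages, self.growth)

        self.year = 0
        self.release_start: Optional[int] = (
            1 if (self.scen.scenario != Scenario.INVASION
                  and self.scen.release_fraction > 0) else None)
        self.records: list[YearRecord] = []
        self.state = self.initialize()
        self._record()

    # -- setup -------------------------------------------------------------

    def _setup_expected_competition(self) -> None:
        comp, growth, arena = self.comp, self.growth, self.arena
        ec = lambda cap, exert=1.0: expected_competition(
            cap, arena, comp, growth, exert, self._p_ages)
        self._native_on_fire: Optional[float] = None
        if self.scen.scenario == Scenario.NATIVE_COEXIST:
            f = comp.interspecies_factor
            fire_terms = ec(comp.n_monogyne) + ec(comp.n_polygyne, comp.polygyne_exert_factor)
            self._e_fire = fire_terms + f * ec(comp.n_native)
            self._e_native = f * fire_terms + ec(comp.n_native)
        elif self.scen.scenario == Scenario.INVASION:
            # asymmetric pressure: only native-on-fire competition is reduced
            self._native_on_fire = comp.interspecies_factor
            self._e_fire = ec(comp.n_monogyne)
            self._e_native = ec(comp.n_native)
        else:
            self._e_fire = ec(comp.n_monogyne)
            self._e_native = ec(comp.n_native)

    def _init_group(self, n: int, form: int, species: int,
                    x_lo: float, x_hi: float) -> ColonyState:
        rng = self.rng
        x = rng.uniform(x_lo, x_hi, n)
        y = rng.uniform(0.0, self.arena.side, n)
        ages = rng.choice(np.arange(2, 2 + len(self._p_ages)), size=n,
                          p=self._p_ages).astype(np.int32)
        i8 = lambda v: np.full(n, v, dtype=np.int8)
        two_target = self.cfg.uses_drive_site
        ds = i8(gn.DS_W) if two_target else i8(gn.NO_ALLELE)
        if form == _POLY:
            qs1, qs2 = i8(gn.SB), i8(gn.Sb)
            ms = np.where(rng.random(n) < 0.5, gn.Sb, gn.SB).astype(np.int8)
        else:
            qs1, qs2, ms = i8(gn.SB), i8(gn.SB), i8(gn.SB)
        return ColonyState(
            x=x, y=y, age=ages, form=i8(form), species=i8(species),
            qf1=i8(gn.W), qf2=i8(gn.W), qs1=qs1, qs2=qs2,
            qd1=ds.copy(), qd2=ds.copy(),
            mf=i8(gn.W), ms=ms, md=ds.copy(),
            mated=np.ones(n, dtype=bool),
        )

    def initialize(self) -> ColonyState:
        """Place wild-type colonies with the stationary age distribution."""
        scen = self.scen
        side = self.arena.side
        groups: list[ColonyState] = []
        if scen.scenario == Scenario.INVASION:
            half = scen.invasion_fire_fraction / 2.0
            groups.append(self._init_group(
                scen.init_polygyne, _POLY, _FIRE, 0.0, half * side))
            groups.append(self._init_group(
                scen.init_monogyne, _MONO, _FIRE, half * side,
                scen.invasion_fire_fraction * side))
            groups.append(self._init_group(
                scen.init_native, _MONO, _NATIVE,
                scen.invasion_fire_fraction * side, side))
        else:
            groups.append(self._init_group(scen.init_monogyne, _MONO, _FIRE, 0.0, side))
            groups.append(self._init_group(scen.init_polygyne, _POLY, _FIRE, 0.0, side))
            if scen.init_native:
                groups.append(self._init_group(scen.init_native, _MONO, _NATIVE, 0.0, side))
        return ColonyState.concatenate(groups)

    # -- shared helpers ----------------------------------------------------

    def _release_active(self) -> bool:
        return (self.scen.release_fraction > 0
                and self.release_start is not None
                and self.release_start <= self.year < self.release_start + self.scen.release_years)

    def _check_invasion_trigger(self) -> None:
        if (self.scen.scenario != Scenario.INVASION or self.release_start is not None
                or self.scen.release_fraction <= 0):
            return
        s = self.state
        side = self.arena.side
        lo = (self.scen.invasion_trigger_slice - 1) / 10.0 * side
        hi = lo + 0.05 * side
        band = (s.x >= lo) & (s.x < hi) & (s.age >= 1)
        if not np.any(band):
            return
        from .metrics import _biomass_values  # internal reuse

        vals = _biomass_values(s.age[band], s.form[band], self.growth)
        fire = s.species[band] == _FIRE
        total = vals.sum()
        if total > 0 and vals[fire].sum() / total >= self.scen.invasion_trigger_fraction:
            self.release_start = self.year

    def _biomass(self, age, form) -> np.ndarray:
        mass = np.where(form == _POLY,
                        2.0 * MASS_FACTOR_POLYGYNE, MASS_FACTOR_MONOGYNE)
        return self._size_tab[np.minimum(age, self._size_tab.size - 1)] * mass

    def _mate_pool(self, s: ColonyState, species: int) -> _MatePool:
        idx = np.flatnonzero((s.age >= 2) & s.mated & (s.species == species))
        if idx.size == 0:
            return _MatePool(idx, np.empty(0), np.empty(0), np.empty(0))
        fec = gn.batch_fecundity(s.qf1[idx], s.qf2[idx], s.qd1[idx], s.qd2[idx], self.cfg)
        w = self._biomass(s.age[idx], s.form[idx]) * fec
        w[s.form[idx] == _POLY] *= self.scen.polygyne_male_rate
        return _MatePool(idx, w, s.x[idx].copy(), s.y[idx].copy())

    def _sample_fathers(self, pool: _MatePool, qx: np.ndarray, qy: np.ndarray,
                        radius: np.ndarray) -> np.ndarray:
        """One biomass-and-fitness weighted father draw per queen.

        Candidates are the pool colonies within the queen's search radius
        (falling back to the nearest ``mate_fallback_k`` when the radius is
        empty); returns state indices, -1 where no candidate exists.
        Sampling rejects global draws outside the radius, which is exactly
        the radius-restricted weighted distribution, then finishes the rare
        stragglers with an explicit local enumeration.
        """
        m = qx.shape[0]
        res = np.full(m, -1, dtype=np.int64)
        if pool.total <= 0.0 or m == 0:
            return res
        unresolved = np.arange(m)
        npool = pool.idx.size
        for _ in range(30):
            if unresolved.size == 0:
                return res
            u = self.rng.random(unresolved.size)
            k = np.minimum(np.searchsorted(pool.cum, u * pool.total), npool - 1)
            ok = ((qx[unresolved] - pool.px[k]) ** 2
                  + (qy[unresolved] - pool.py[k]) ** 2) <= radius[unresolved] ** 2
            res[unresolved[ok]] = pool.idx[k[ok]]
            unresolved = unresolved[~ok]
        for q in unresolved:
            local = np.sort(np.asarray(
                pool.tree.query_ball_point((qx[q], qy[q]), radius[q]), dtype=np.int64))
            if local.size == 0:
                k = min(self.scen.mate_fallback_k, npool)
                local = np.sort(np.atleast_1d(pool.tree.query((qx[q], qy[q]), k=k)[1]))
            wl = pool.w[local]
            tot = wl.sum()
            if tot <= 0.0:
                continue
            pick = int(np.searchsorted(np.cumsum(wl), self.rng.random() * tot))
            res[q] = int(pool.idx[local[min(pick, local.size - 1)]])
        return res

    def _make_sons(self, s: ColonyState, fathers: np.ndarray):
        """Males are germline gametes of the father colony's queen, with her
        embryo-resistance activity applied; returns (mf, ms, md, viable)."""
        cfg = self.cfg
        gf, gs, gd = gn.batch_gametes(
            s.qf1[fathers], s.qf2[fathers], s.qs1[fathers], s.qs2[fathers],
            s.qd1[fathers], s.qd2[fathers], cfg, self.rng)
        has_drive = gn.batch_carries_drive(
            s.qf1[fathers], s.qf2[fathers], s.qd1[fathers], s.qd2[fathers])
        gf = gn.batch_embryo_resistance(gf, has_drive, cfg, "fertility", self.rng)
        if cfg.uses_drive_site:
            gd = gn.batch_embryo_resistance(gd, has_drive, cfg, "drive_site", self.rng)
            viable = gd != gn.DS_R
        else:
            viable = np.ones(fathers.size, dtype=bool)
        return gf, gs, gd, viable

    def _released_males(self, n: int):
        social = np.where(self.rng.random(n) < self.scen.release_sb_fraction,
                          gn.Sb, gn.SB).astype(np.int8)
        if self.cfg.uses_drive_site:
            return (np.full(n, gn.W, np.int8), social, np.full(n, gn.DS_D, np.int8))
        return (np.full(n, gn.D, np.int8), social, np.full(n, gn.NO_ALLELE, np.int8))

    def _select_mate_single(self, s: ColonyState, pool: _MatePool, pos,
                            queen_form: int, species: int) -> Optional[tuple[int, int, int]]:
        release = self._release_active() and species == _FIRE
        q_rel = self.scen.release_fraction / (1.0 + self.scen.release_fraction)
        sigma = self._sigma_poly if queen_form == _POLY else self._sigma_mono
        radius = np.array([self.scen.mate_radius_factor * sigma])
        px = np.array([pos[0]])
        py = np.array([pos[1]])
        for _ in range(self.scen.mate_attempts):
            if release and self.rng.random() < q_rel:
                mf, ms, md = self._released_males(1)
            else:
                fa = self._sample_fathers(pool, px, py, radius)
                if fa[0] < 0:
                    continue
                mf, ms, md, ok = self._make_sons(s, fa[:1])
                if not ok[0]:
                    continue
            if queen_form == _MONO and ms[0] == gn.Sb:
                continue  # monogyne queens only accept SB males
            return int(mf[0]), int(ms[0]), int(md[0])
        return None

    # -- yearly cycle ------------------------------------------------------

    def _reproduce(self, s: ColonyState) -> ColonyState:
        cfg = self.cfg
        moms = np.flatnonzero((s.age >= 2) & s.mated)
        if moms.size == 0:
            return ColonyState.empty()
        fec = gn.batch_fecundity(s.qf1[moms], s.qf2[moms], s.qd1[moms], s.qd2[moms], cfg)
        means = queen_production_mean(s.age[moms], fec, self.growth)
        counts = self.rng.poisson(means)
        rep = np.repeat(moms, counts)
        if rep.size == 0:
            return ColonyState.empty()

        gf, gs, gd = gn.batch_gametes(
            s.qf1[rep], s.qf2[rep], s.qs1[rep], s.qs2[rep],
            s.qd1[rep], s.qd2[rep], cfg, self.rng)
        pf, ps, pd = s.mf[rep].copy(), s.ms[rep].copy(), s.md[rep].copy()
        momdrive = gn.batch_carries_drive(s.qf1[rep], s.qf2[rep], s.qd1[rep], s.qd2[rep])
        gf = gn.batch_embryo_resistance(gf, momdrive, cfg, "fertility", self.rng)
        pf = gn.batch_embryo_resistance(pf, momdrive, cfg, "fertility", self.rng)
        if cfg.uses_drive_site:
            gd = gn.batch_embryo_resistance(gd, momdrive, cfg, "drive_site", self.rng)
            pd = gn.batch_embryo_resistance(pd, momdrive, cfg, "drive_site", self.rng)

        viable = gn.batch_female_viable(gs, ps, gd, pd, cfg)
        fertile = gn.batch_female_fertile(gf, pf, cfg)  # sterile queens found no colony
        off_form = gn.batch_social_form(gf, pf, gs, ps, gd, pd, cfg)
        mother_poly = s.form[rep] == _POLY
        accepted = gn.batch_greenbeard_survives(mother_poly, off_form, gf, pf, gd, pd, cfg)
        keep = viable & fertile & accepted
        if not np.any(keep):
            return ColonyState.empty()
        rep, gf, pf, gs, ps, gd, pd, off_form = (
            arr[keep] for arr in (rep, gf, pf, gs, ps, gd, pd, off_form))

        sigma = np.where(off_form == _POLY, self._sigma_poly, self._sigma_mono)
        x, y = dispersal_draw_batch(s.x[rep], s.y[rep], sigma, self.arena, self.rng)
        n = rep.size
        no = np.full(n, gn.NO_ALLELE, dtype=np.int8)
        return ColonyState(
            x=x, y=y, age=np.zeros(n, dtype=np.int32),
            form=off_form.astype(np.int8), species=s.species[rep].copy(),
            qf1=gf.astype(np.int8), qf2=pf.astype(np.int8),
            qs1=gs.astype(np.int8), qs2=ps.astype(np.int8),
            qd1=gd.astype(np.int8) if cfg.uses_drive_site else no.copy(),
            qd2=pd.astype(np.int8) if cfg.uses_drive_site else no.copy(),
            mf=no.copy(), ms=no.copy(), md=no.copy(),
            mated=np.zeros(n, dtype=bool),
        )

    def _replacement_candidate(self, s: ColonyState, pos, mother_pool: _MatePool,
                               mate_pool: _MatePool) -> Optional[tuple]:
        """A newly mated polygyne queen to take over a colony, or None."""
        cfg = self.cfg
        radius = np.array([self.scen.mate_radius_factor * self._sigma_poly])
        px = np.array([pos[0]])
        py = np.array([pos[1]])
        for _ in range(self.scen.replacement_attempts):
            fa = self._sample_fathers(mother_pool, px, py, radius)
            if fa[0] < 0:
                return None
            j = fa[:1]
            gf, gs, gd = gn.batch_gametes(
                s.qf1[j], s.qf2[j], s.qs1[j], s.qs2[j], s.qd1[j], s.qd2[j], cfg, self.rng)
            pf, ps, pd = s.mf[j].copy(), s.ms[j].copy(), s.md[j].copy()
            momdrive = gn.batch_carries_drive(s.qf1[j], s.qf2[j], s.qd1[j], s.qd2[j])
            gf = gn.batch_embryo_resistance(gf, momdrive, cfg, "fertility", self.rng)
            pf = gn.batch_embryo_resistance(pf, momdrive, cfg, "fertility", self.rng)
            if cfg.uses_drive_site:
                gd = gn.batch_embryo_resistance(gd, momdrive, cfg, "drive_site", self.rng)
                pd = gn.batch_embryo_resistance(pd, momdrive, cfg, "drive_site", self.rng)
            if not (gn.batch_female_viable(gs, ps, gd, pd, cfg)[0]
                    and gn.batch_female_fertile(gf, pf, cfg)[0]):
                continue
            form = gn.batch_social_form(gf, pf, gs, ps, gd, pd, cfg)[0]
            if form != _POLY:
                continue  # the representative queen must carry the greenbeard trait
            male = self._select_mate_single(s, mate_pool, pos, _POLY, _FIRE)
            if male is None:
                continue
            queen = self._genome_from_codes(
                (int(gf[0]), int(pf[0])), (int(gs[0]), int(ps[0])),
                (int(gd[0]), int(pd[0])))
            mate = self._genome_from_codes((male[0],), (male[1],), (male[2],))
            if gn.viable_daughter_fraction(queen, mate, cfg, SocialForm.POLYGYNE) <= 0.0:
                continue  # e.g. cleave drives: she could never head a polygyne nest
            return (int(gf[0]), int(pf[0]), int(gs[0]), int(ps[0]),
                    int(gd[0]), int(pd[0])), male
        return None

    def _genome_from_codes(self, fert, social, site) -> gn.Genome:
        cfg = self.cfg
        return gn.Genome(
            gn.Ploidy.DIPLOID if len(fert) == 2 else gn.Ploidy.HAPLOID,
            tuple(gn.FertilityAllele(a) for a in fert),
            tuple(gn.SocialAllele(a) for a in social),
            tuple(gn.DriveSiteAllele(a) for a in site) if cfg.uses_drive_site else (),
        )

    def _polygyne_replacement(self, s: ColonyState, alive: np.ndarray) -> None:
        p = self.growth.queen_replacement_prob
        targets = np.flatnonzero((s.form == _POLY) & (s.species == _FIRE)
                                 & (s.age >= 1) & s.mated & alive)
        if targets.size == 0 or p <= 0.0:
            return
        attempts = targets[self.rng.random(targets.size) < p]
        if attempts.size == 0:
            return
        poly_idx = np.flatnonzero((s.form == _POLY) & (s.species == _FIRE)
                                  & (s.age >= 2) & s.mated & alive)
        if poly_idx.size:
            fec = gn.batch_fecundity(s.qf1[poly_idx], s.qf2[poly_idx],
                                     s.qd1[poly_idx], s.qd2[poly_idx], self.cfg)
            wmom = queen_production_mean(s.age[poly_idx], fec, self.growth)
            mother_pool = _MatePool(poly_idx, wmom, s.x[poly_idx].copy(), s.y[poly_idx].copy())
        else:
            mother_pool = _MatePool(poly_idx, np.empty(0), np.empty(0), np.empty(0))
        mate_pool = self._mate_pool(s, _FIRE)
        for i in attempts:
            cand = self._replacement_candidate(s, (s.x[i], s.y[i]), mother_pool, mate_pool)
            if cand is not None:
                (f1, f2, s1, s2, d1, d2), (m1, m2, m3) = cand
                s.qf1[i], s.qf2[i], s.qs1[i], s.qs2[i] = f1, f2, s1, s2
                s.qd1[i], s.qd2[i] = d1, d2
                s.mf[i], s.ms[i], s.md[i] = m1, m2, m3
            elif self.rng.random() < self.growth.replacement_fail_death:
                alive[i] = False

    def _mate_queens(self, s: ColonyState, alive: np.ndarray) -> None:
        queens = np.flatnonzero((s.age == 1) & ~s.mated & alive)
        if queens.size == 0:
            return
        q_rel = self.scen.release_fraction / (1.0 + self.scen.release_fraction)
        for sp in (_FIRE, _NATIVE):
            q = queens[s.species[queens] == sp]
            if q.size == 0:
                continue
            pool = self._mate_pool(s, sp)
            release = self._release_active() and sp == _FIRE
            radius = self.scen.mate_radius_factor * np.where(
                s.form[q] == _POLY, self._sigma_poly, self._sigma_mono)
            active, rad = q, radius
            for _ in range(self.scen.mate_attempts):
                if active.size == 0:
                    break
                n = active.size
                mf = np.full(n, -1, dtype=np.int8)
                ms = np.full(n, -1, dtype=np.int8)
                md = np.full(n, -1, dtype=np.int8)
                got = np.zeros(n, dtype=bool)
                use_rel = (self.rng.random(n) < q_rel) if release else np.zeros(n, dtype=bool)
                ridx = np.flatnonzero(use_rel)
                if ridx.size:
                    rf, rs, rd = self._released_males(ridx.size)
                    mf[ridx], ms[ridx], md[ridx] = rf, rs, rd
                    got[ridx] = True
                nidx = np.flatnonzero(~use_rel)
                if nidx.size:
                    fa = self._sample_fathers(pool, s.x[active[nidx]], s.y[active[nidx]],
                                              rad[nidx])
                    have = fa >= 0
                    sub = nidx[have]
                    if sub.size:
                        gf, gsoc, gd, ok = self._make_sons(s, fa[have])
                        mf[sub], ms[sub], md[sub] = gf, gsoc, gd
                        got[sub] = ok
                # monogyne queens reject Sb-bearing males and retry
                got &= ~((s.form[active] == _MONO) & (ms == gn.Sb))
                si = active[got]
                s.mf[si], s.ms[si], s.md[si] = mf[got], ms[got], md[got]
                s.mated[si] = True
                active, rad = active[~got], rad[~got]
            alive[active] = False  # unmated queens cannot found a working colony
            if sp == _FIRE and self.cfg.variant == DriveVariant.CLEAVE_SB:
                # a drive SB/Sb queen mated to an Sb male: every worker would be
                # an Sb homozygote, so the colony is nonviable
                doomed = q[s.mated[q]
                           & (s.ms[q] == gn.Sb)
                           & ((s.qf1[q] == gn.D) | (s.qf2[q] == gn.D))
                           & (s.qs1[q] != s.qs2[q])]
                alive[doomed] = False

    def _survival(self, s: ColonyState) -> np.ndarray:
        comp, growth = self.comp, self.growth
        actual = actual_competition(
            s.x, s.y, s.age, s.form, s.species, comp, growth,
            native_on_fire_factor=self._native_on_fire)
        expected = np.where(s.species == _NATIVE, self._e_native, self._e_fire)
        R = np.maximum(actual / expected, 1e-12)

        survive = np.ones(s.n, dtype=bool)
        u = self.rng.random(s.n)

        newborn = s.age == 0
        if np.any(newborn):
            p0 = age0_survival(R[newborn], comp.low_density_growth, comp.age0_base)
            survive[newborn] = u[newborn] < p0
        adults = ~newborn
        if np.any(adults):
            size = self._size_tab[np.minimum(s.age[adults], self._size_tab.size - 1)]
            ceiling = np.where((s.form[adults] == _POLY) & (s.species[adults] == _FIRE),
                               comp.survival_ceiling_polygyne,
                               comp.survival_ceiling_monogyne)
            pa = ceiling - comp.survival_amplitude * np.exp(
                -comp.survival_rate_constant * size / R[adults])
            survive[adults] = u[adults] < np.clip(pa, 0.0, 1.0)

        # age-related death after density survival
        poly_fire = (s.form == _POLY) & (s.species == _FIRE)
        survive &= ~(poly_fire & (s.age >= growth.max_age_polygyne))
        mono_like = ~poly_fire
        survive &= ~(mono_like & (s.age >= growth.max_age_monogyne))
        at6 = mono_like & (s.age == growth.age6)
        survive[at6] &= self.rng.random(int(at6.sum())) < 1.0 - growth.age6_death
        return survive

    def step(self) -> None:
        """Advance the simulation by one year."""
        self.year += 1
        s = self.state
        s.age += 1
        self._check_invasion_trigger()

        offspring = self._reproduce(s)
        alive = np.ones(s.n, dtype=bool)
        self._polygyne_replacement(s, alive)
        self._mate_queens(s, alive)

        merged = ColonyState.concatenate([s.select(alive), offspring])
        survive = self._survival(merged)
        self.state = merged.select(survive)
        self._record()

    def _drive_allele_count(self, s: ColonyState) -> int:
        fire = s.species == _FIRE
        if self.cfg.uses_drive_site:
            return int((s.qd1[fire] == gn.DS_D).sum() + (s.qd2[fire] == gn.DS_D).sum()
                       + ((s.md[fire] == gn.DS_D) & s.mated[fire]).sum())
        return int((s.qf1[fire] == gn.D).sum() + (s.qf2[fire] == gn.D).sum()
                   + ((s.mf[fire] == gn.D) & s.mated[fire]).sum())

    def _record(self) -> None:
        s = self.state
        fire = s.species == _FIRE
        poly = s.form == _POLY
        bm, bp, bn = biomass_by_group(s.age, s.form, s.species, self.growth)
        rec = YearRecord(
            year=self.year,
            n_monogyne=int((fire & ~poly & (s.age >= 2)).sum()),
            n_polygyne=int((fire & poly & (s.age >= 2)).sum()),
            n_native=int((~fire & (s.age >= 2)).sum()),
            n_monogyne_all=int((fire & ~poly & (s.age >= 1)).sum()),
            n_polygyne_all=int((fire & poly & (s.age >= 1)).sum()),
            n_native_all=int((~fire & (s.age >= 1)).sum()),
            biomass_monogyne=bm, biomass_polygyne=bp, biomass_native=bn,
            biomass_fire=bm + bp,
        )
        if np.any(fire):
            freqs = allele_frequencies(
                s.qf1[fire], s.qf2[fire], s.qs1[fire], s.qs2[fire],
                s.mf[fire], s.ms[fire], s.mated[fire],
                s.qd1[fire], s.qd2[fire], s.md[fire])
            rec.drive_frequency = freqs["drive"]
            rec.resistance_frequency = freqs["resistance"]
            rec.sb_frequency = freqs["sb"]
        grown = fire & (s.age >= 1)
        if int(grown.sum()) >= 2:
            rec.nn_index = nearest_neighbor_index(
                np.column_stack([s.x[grown], s.y[grown]]), self.arena.area)
        rec.fire_slices = tuple(slice_biomass(
            s.x[fire], s.age[fire], s.form[fire], self.arena.side, 10, self.growth))
        rec.native_slices = tuple(slice_biomass(
            s.x[~fire], s.age[~fire], s.form[~fire], self.arena.side, 10, self.growth))
        self.records.append(rec)

    def run(self) -> RunResult:
        termination = "year_limit"
        while self.year < self.scen.years:
            self.step()
            s = self.state
            if not np.any(s.species == _FIRE):
                termination = "fire_eliminated"
                break
            if (self.release_start is not None
                    and self.year >= self.release_start + self.scen.release_years
                    and self._drive_allele_count(s) == 0):
                termination = "drive_lost"
                break
        return RunResult(
            records=records_to_frame(self.records),
            termination=termination,
            termination_year=self.year,
            release_start=self.release_start,
            config=self.config,
            seed=self.seed,
        )


def run_replicates(config: RunConfig, n_replicates: Optional[int] = None,
                   base_seed: Optional[int] = None) -> list[RunResult]:
    """Run independent replicates seeded from (base_seed, replicate index)."""
    n = config.replicates if n_replicates is None else n_replicates
    base = config.seed if base_seed is None else base_seed
    results = []
    for rep in range(n):
        seed = int(np.random.SeedSequence([base, rep]).generate_state(1)[0] % (2**31))
        results.append(Simulation(config, seed=seed).run())
    return results
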