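"""Discrete-generation panmictic haplodiploid model of suppression drives.

Tracks exact genotype frequencies of diploid females and haploid males at
the drive-targeted loci under random mating: daughters combine a maternal
germline gamete (homing and resistance applied) with a paternal allele set,
sons arise from unfertilized maternal gametes, and maternally deposited
Cas9 mutates offspring wild-type alleles at the embryo resistance rate.
Nonviable genotypes are removed and frequencies renormalized per sex.

The *genetic load* of a drive is the fractional reduction, relative to an
all-wild population, of per-female production of viable daughters weighted
by female fecundity — for the standard drive simply one minus the mean
female fitness at equilibrium.  A deterministic population is eliminated
when the load exceeds 1 - 1/g, with g the low-density growth rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .demography import monogyne_generation_time, polygyne_generation_time  # noqa: F401
from .genetics import (
    DriveConfig,
    DriveVariant,
    FertilityAllele,
    Genome,
    Ploidy,
    SocialAllele,
    SocialForm,
    DriveSiteAllele,
    embryo_haplotype_distribution,
    fecundity_multiplier,
    gamete_distribution,
    greenbeard_survives,
    is_female_viable,
    is_male_viable,
    social_form,
)

__all__ = [
    "GenotypeFrequencies",
    "LoadResult",
    "PanmicticModel",
    "PanmicticExtinction",
    "next_generation",
    "equilibrium_genetic_load",
    "required_genetic_load",
    "load_sweep",
]

_SOCIAL_VARIANTS = (
    DriveVariant.POLYGYNE_DRIVE,
    DriveVariant.GREENBEARD_DRIVE,
    DriveVariant.CLEAVE_SB,
    DriveVariant.CLEAVE_Sb,
)


class PanmicticExtinction(RuntimeError):
    """Raised when the fertile female pool is empty (population collapse)."""


@dataclass
class GenotypeFrequencies:
    """Per-sex genotype frequency vectors (aligned with a model's indices)."""

    females: np.ndarray
    males: np.ndarray

    def normalized(self) -> "GenotypeFrequencies":
        return GenotypeFrequencies(self.females / self.females.sum(),
                                   self.males / self.males.sum())


@dataclass(frozen=True)
class LoadResult:
    load: float
    generations: int
    converged: bool
    drive_lost: bool
    drive_frequency: float


def _fertility_alleles(cfg: DriveConfig) -> list[FertilityAllele]:
    if cfg.uses_drive_site:
        return [FertilityAllele.WILD, FertilityAllele.RES_NONFUNC]
    if cfg.variant == DriveVariant.DOMINANT_STERILE:
        return [FertilityAllele.WILD, FertilityAllele.DRIVE, FertilityAllele.RES_DOMSTERILE]
    return [FertilityAllele.WILD, FertilityAllele.DRIVE, FertilityAllele.RES_NONFUNC]


class PanmicticModel:
    """Exact genotype-frequency recursion for one drive configuration.

    Builds the haplotype and genotype spaces for the active loci and
    precomputes the daughter transition tensor, after which each generation
    is a pair of tensor contractions.
    """

    def __init__(self, cfg: DriveConfig):
        self.cfg = cfg
        self.social_locus = cfg.variant in _SOCIAL_VARIANTS

        fert = _fertility_alleles(cfg)
        soc = [SocialAllele.SB, SocialAllele.Sb] if self.social_locus else [SocialAllele.SB]
        site = ([DriveSiteAllele.WILD, DriveSiteAllele.DRIVE_RESCUE, DriveSiteAllele.RES_NONFUNC]
                if cfg.uses_drive_site else [None])

        self.haplotypes: list[Genome] = []
        for f, s, d in itertools.product(fert, soc, site):
            self.haplotypes.append(
                Genome(Ploidy.HAPLOID, (f,), (s,), (d,) if d is not None else ())
            )
        self._h_index = {h: i for i, h in enumerate(self.haplotypes)}
        H = len(self.haplotypes)

        self.female_genotypes: list[Genome] = []
        self._pair_index = np.zeros((H, H), dtype=np.int64)
        pairs: dict[tuple[int, int], int] = {}
        for i in range(H):
            for j in range(H):
                key = (min(i, j), max(i, j))
                if key not in pairs:
                    hi, hj = self.haplotypes[key[0]], self.haplotypes[key[1]]
                    g = Genome(
                        Ploidy.DIPLOID,
                        (hi.fertility[0], hj.fertility[0]),
                        (hi.social[0], hj.social[0]),
                        (hi.drive_site[0], hj.drive_site[0]) if cfg.uses_drive_site else (),
                    )
                    pairs[key] = len(self.female_genotypes)
                    self.female_genotypes.append(g)
                self._pair_index[i, j] = pairs[key]
        G = len(self.female_genotypes)

        self.fecundity = np.array(
            [fecundity_multiplier(g, cfg) for g in self.female_genotypes])
        self.female_viable = np.array(
            [is_female_viable(g, cfg) for g in self.female_genotypes], dtype=bool)
        self.male_viable = np.array(
            [is_male_viable(h, cfg) for h in self.haplotypes], dtype=bool)
        self._drive_count_f = np.array([
            g.fertility.count(FertilityAllele.DRIVE)
            + g.drive_site.count(DriveSiteAllele.DRIVE_RESCUE)
            for g in self.female_genotypes], dtype=float)
        self._drive_count_m = np.array([
            h.fertility.count(FertilityAllele.DRIVE)
            + h.drive_site.count(DriveSiteAllele.DRIVE_RESCUE)
            for h in self.haplotypes], dtype=float)

        # embryo-resistance matrix E[h, h'] (drive mothers only)
        E = np.zeros((H, H))
        for i, h in enumerate(self.haplotypes):
            for h2, p in embryo_haplotype_distribution(h, cfg).items():
                E[i, self._h_index[h2]] += p
        identity = np.eye(H)

        # maternal gamete-after-embryo distribution A[g, h]
        A = np.zeros((G, H))
        mother_drive = np.zeros(G, dtype=bool)
        for gi, g in enumerate(self.female_genotypes):
            mother_drive[gi] = g.carries_drive()
            for h, p in gamete_distribution(g, cfg).items():
                A[gi, self._h_index[h]] += p
            if mother_drive[gi]:
                A[gi] = A[gi] @ E
        self._A = A

        # daughter keep mask: viability and (social variants) greenbeard cull
        keep_gg = np.zeros((G, G), dtype=bool)
        for gi, mother in enumerate(self.female_genotypes):
            if self.social_locus:
                mform = social_form(mother, cfg)
            else:
                mform = SocialForm.MONOGYNE
            for di, daughter in enumerate(self.female_genotypes):
                keep_gg[gi, di] = self.female_viable[di] and greenbeard_survives(
                    mform, daughter, cfg)

        # daughter tensor D[g, hf, g']: mass of kept daughters per father haplotype
        D = np.zeros((G, H, G))
        for gi in range(G):
            pat = E if mother_drive[gi] else identity
            # daughters combine maternal h1 (A) with paternal h2 (pat row of hf)
            joint = np.einsum("a,fb->fab", A[gi], pat)  # [hf, h1, h2]
            for f in range(H):
                np.add.at(D[gi, f], self._pair_index.ravel(),
                          joint[f].ravel())
            D[gi] *= keep_gg[gi][None, :]
        self._D = D
        # son distribution S[g, h'] (male-viable mass only)
        self._S = A * self.male_viable[None, :]

    # -- states ------------------------------------------------------------

    def wild_state(self, sb_frequency: float = 0.5) -> GenotypeFrequencies:
        """All-wild starting state.

        For social-form variants the population starts with the given Sb
        male frequency and the corresponding mix of SB/SB and SB/Sb females;
        otherwise every individual is wild-type.
        """
        F = np.zeros(len(self.female_genotypes))
        M = np.zeros(len(self.haplotypes))
        wild_f = FertilityAllele.WILD

        def hap(s: SocialAllele) -> Genome:
            return Genome(Ploidy.HAPLOID, (wild_f,), (s,),
                          (DriveSiteAllele.WILD,) if self.cfg.uses_drive_site else ())

        if self.social_locus:
            hb, hs = hap(SocialAllele.SB), hap(SocialAllele.Sb)
            M[self._h_index[hb]] = 1.0 - sb_frequency
            M[self._h_index[hs]] = sb_frequency
            F[self._pair_index[self._h_index[hb], self._h_index[hb]]] = 1.0 - sb_frequency
            F[self._pair_index[self._h_index[hb], self._h_index[hs]]] = sb_frequency
        else:
            h = hap(SocialAllele.SB)
            M[self._h_index[h]] = 1.0
            F[self._pair_index[self._h_index[h], self._h_index[h]]] = 1.0
        return GenotypeFrequencies(F, M)

    def introduce_drive_males(self, state: GenotypeFrequencies,
                              fraction: float = 0.01) -> GenotypeFrequencies:
        males = state.males * (1.0 - fraction)
        if self.social_locus:
            for s, w in ((SocialAllele.SB, 0.5), (SocialAllele.Sb, 0.5)):
                males[self._h_index[Genome.drive_male(self.cfg, s)]] += fraction * w
        else:
            males[self._h_index[Genome.drive_male(self.cfg)]] += fraction
        return GenotypeFrequencies(state.females.copy(), males)

    # -- dynamics ----------------------------------------------------------

    def reproductive_weights(self, state: GenotypeFrequencies) -> np.ndarray:
        return state.females * self.fecundity

    def output(self, state: GenotypeFrequencies) -> float:
        """Per-female production of kept daughters (fecundity-weighted)."""
        Wv = self.reproductive_weights(state)
        kept = np.einsum("g,f,gfd->", Wv, state.males, self._D)
        return float(kept)

    def next_generation(self, state: GenotypeFrequencies) -> GenotypeFrequencies:
        Wv = self.reproductive_weights(state)
        if Wv.sum() <= 0.0:
            raise PanmicticExtinction("no fertile females remain")
        daughters = np.einsum("g,f,gfd->d", Wv, state.males, self._D)
        sons = Wv @ self._S
        if daughters.sum() <= 0.0 or sons.sum() <= 0.0:
            raise PanmicticExtinction("no viable offspring produced")
        return GenotypeFrequencies(daughters / daughters.sum(), sons / sons.sum())

    def drive_frequency(self, state: GenotypeFrequencies) -> float:
        """Drive allele frequency over female (2n) and male (n) genomes."""
        f = float(state.females @ self._drive_count_f)
        m = float(state.males @ self._drive_count_m)
        return (f + m) / 3.0

    def genetic_load(self, state: GenotypeFrequencies,
                     reference: Optional[float] = None) -> float:
        ref = self._reference_output() if reference is None else reference
        return 1.0 - self.output(state) / ref

    def _reference_output(self, sb_frequency: float = 0.5) -> float:
        state = self.wild_state(sb_frequency)
        if self.social_locus:
            state = _iterate_to_equilibrium(self, state, tol=1e-12, max_gens=10_000)[0]
        return self.output(state)


@lru_cache(maxsize=32)
def _model(cfg: DriveConfig) -> PanmicticModel:
    return PanmicticModel(cfg)


def next_generation(freqs: GenotypeFrequencies, cfg: DriveConfig) -> GenotypeFrequencies:
    """One generation of the exact genotype-frequency recursion."""
    return _model(cfg).next_generation(freqs)


def _iterate_to_equilibrium(model: PanmicticModel, state: GenotypeFrequencies,
                            tol: float, max_gens: int):
    prev = state
    prev2 = None
    for gen in range(1, max_gens + 1):
        nxt = model.next_generation(prev)
        delta = max(np.abs(nxt.females - prev.females).max(),
                    np.abs(nxt.males - prev.males).max())
        if delta < tol:
            return nxt, gen, True
        if prev2 is not None:
            d2 = max(np.abs(nxt.females - prev2.females).max(),
                     np.abs(nxt.males - prev2.males).max())
            if d2 < tol:  # settled into a 2-cycle; report the cycle point
                return nxt, gen, True
        prev2 = prev
        prev = nxt
    return prev, max_gens, False


def equilibrium_genetic_load(cfg: DriveConfig, introduction: float = 0.01,
                             tol: float = 1e-9, max_gens: int = 100_000,
                             sb_frequency: float = 0.5) -> LoadResult:
    """Iterate from a small drive-male introduction to the drive equilibrium.

    The load is evaluated at the converged state; if the drive is lost the
    result is flagged and the load at the peak-drive-frequency generation
    is reported instead.
    """
    model = _model(cfg)
    state = model.wild_state(sb_frequency)
    if model.social_locus:
        state = _iterate_to_equilibrium(model, state, tol=1e-12, max_gens=10_000)[0]
    reference = model.output(state)
    state = model.introduce_drive_males(state, introduction)

    peak_freq = -1.0
    peak_load = 0.0
    prev = state
    prev2 = None
    converged = False
    gen = 0
    try:
        for gen in range(1, max_gens + 1):
            nxt = model.next_generation(prev)
            freq = model.drive_frequency(nxt)
            if freq > peak_freq:
                peak_freq = freq
                peak_load = model.genetic_load(nxt, reference)
            delta = max(np.abs(nxt.females - prev.females).max(),
                        np.abs(nxt.males - prev.males).max())
            stop = delta < tol
            if not stop and prev2 is not None:
                d2 = max(np.abs(nxt.females - prev2.females).max(),
                         np.abs(nxt.males - prev2.males).max())
                stop = d2 < tol
            prev2 = prev
            prev = nxt
            if stop:
                converged = True
                break
    except PanmicticExtinction:
        return LoadResult(1.0, gen, True, False, peak_freq)

    final_freq = model.drive_frequency(prev)
    drive_lost = final_freq < 1e-6
    load = peak_load if drive_lost else model.genetic_load(prev, reference)
    return LoadResult(float(load), gen, converged, drive_lost, float(final_freq))


def required_genetic_load(g: float) -> float:
    """Deterministic elimination threshold 1 - 1/g for growth rate g > 1."""
    if g <= 1.0:
        raise ValueError("low-density growth rate must exceed 1")
    return 1.0 - 1.0 / g


def load_sweep(conversions: Iterable[float], germline_res_rates: Iterable[float],
               base: DriveConfig = DriveConfig(), **load_kwargs) -> pd.DataFrame:
    """Equilibrium genetic load over a conversion x germline-resistance grid.

    Returns a tidy frame with one row per grid point, mirroring the drive
    performance sweeps used to compare standard and dominant-sterile drives.
    """
    from dataclasses import replace as dc_replace

    rows = []
    for c in conversions:
        for r in germline_res_rates:
            cfg = dc_replace(base, conversion_rate=float(c), germline_res_rate=float(r))
            res = equilibrium_genetic_load(cfg, **load_kwargs)
            rows.append({
                "conversion_rate": float(c),
                "germline_res_rate": float(r),
                "total_cut_rate": cfg.total_cut_rate,
                "genetic_load": res.load,
                "drive_lost": res.drive_lost,
                "generations": res.generations,
            })
    return pd.DataFrame(rows)
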