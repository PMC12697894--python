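"""Allele representation and inheritance rules for homing suppression drives.

Fire ants are haplodiploid: queens are diploid, males develop from
unfertilized eggs and are haploid.  The drive sits at a recessive female
fertility locus (or, for the two-target variants, at a separate essential
"drive site" whose extra gRNAs cut the distant fertility gene).  A second,
independently segregating locus carries the social supergene alleles SB/Sb:
Sb is dominant polygyne and Sb/Sb females are lethal.

The module exposes two parallel APIs over the same rules:

* scalar operations on :class:`Genome` objects, backed by exact per-locus
  probability enumeration (:func:`gamete_distribution`), used by the
  deterministic panmictic recursion and as the oracle in tests;
* ``batch_*`` kernels operating on integer-coded numpy allele arrays, used
  by the spatial engine.  A property test pins the kernels to the
  enumeration so the two routes cannot drift apart.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "FertilityAllele",
    "SocialAllele",
    "DriveSiteAllele",
    "DriveVariant",
    "SocialForm",
    "Ploidy",
    "Genome",
    "DriveConfig",
    "gamete_distribution",
    "female_germline_gamete",
    "apply_embryo_resistance",
    "embryo_haplotype_distribution",
    "is_female_fertile",
    "is_female_viable",
    "is_male_viable",
    "social_form",
    "greenbeard_survives",
    "fecundity_multiplier",
    "viable_daughter_fraction",
]


class FertilityAllele(enum.IntEnum):
    """States at the female-fertility locus."""

    WILD = 0
    DRIVE = 1
    RES_NONFUNC = 2
    RES_DOMSTERILE = 3


class SocialAllele(enum.IntEnum):
    SB = 0
    Sb = 1


class DriveSiteAllele(enum.IntEnum):
    """States at the essential drive-site gene (two-target variants only)."""

    WILD = 0
    DRIVE_RESCUE = 1
    RES_NONFUNC = 2


class DriveVariant(str, enum.Enum):
    STANDARD = "standard"
    DOMINANT_STERILE = "dominant_sterile"
    TWO_TARGET_HAPLOSUFFICIENT = "two_target_haplosufficient"
    TWO_TARGET_HAPLOLETHAL = "two_target_haplolethal"
    POLYGYNE_DRIVE = "polygyne_drive"
    GREENBEARD_DRIVE = "greenbeard_drive"
    CLEAVE_SB = "cleave_SB"
    CLEAVE_Sb = "cleave_Sb"


_TWO_TARGET = (DriveVariant.TWO_TARGET_HAPLOSUFFICIENT, DriveVariant.TWO_TARGET_HAPLOLETHAL)
_SOCIAL_VARIANTS = (
    DriveVariant.POLYGYNE_DRIVE,
    DriveVariant.GREENBEARD_DRIVE,
    DriveVariant.CLEAVE_SB,
    DriveVariant.CLEAVE_Sb,
)


class SocialForm(enum.IntEnum):
    MONOGYNE = 0
    POLYGYNE = 1


class Ploidy(enum.IntEnum):
    HAPLOID = 1
    DIPLOID = 2


@dataclass(frozen=True)
class Genome:
    """Genotype of a queen (diploid) or a male / gamete (haploid).

    ``fertility`` and ``social`` hold 1 (haploid) or 2 (diploid) alleles.
    ``drive_site`` is empty unless a two-target variant is active.
    """

    ploidy: Ploidy
    fertility: tuple[FertilityAllele, ...]
    social: tuple[SocialAllele, ...]
    drive_site: tuple[DriveSiteAllele, ...] = ()

    def __post_init__(self) -> None:
        n = int(self.ploidy)
        if len(self.fertility) != n or len(self.social) != n:
            raise ValueError("allele counts must match ploidy")
        if self.drive_site and len(self.drive_site) != n:
            raise ValueError("drive_site allele count must match ploidy")

    @property
    def is_diploid(self) -> bool:
        return self.ploidy == Ploidy.DIPLOID

    def carries_drive(self) -> bool:
        return FertilityAllele.DRIVE in self.fertility or (
            DriveSiteAllele.DRIVE_RESCUE in self.drive_site
        )

    @staticmethod
    def wild_diploid(social: tuple[SocialAllele, SocialAllele] = (SocialAllele.SB, SocialAllele.SB),
                     two_target: bool = False) -> "Genome":
        return Genome(
            Ploidy.DIPLOID,
            (FertilityAllele.WILD, FertilityAllele.WILD),
            social,
            (DriveSiteAllele.WILD, DriveSiteAllele.WILD) if two_target else (),
        )

    @staticmethod
    def wild_haploid(social: SocialAllele = SocialAllele.SB, two_target: bool = False) -> "Genome":
        return Genome(
            Ploidy.HAPLOID,
            (FertilityAllele.WILD,),
            (social,),
            (DriveSiteAllele.WILD,) if two_target else (),
        )

    @staticmethod
    def drive_male(cfg: "DriveConfig", social: SocialAllele = SocialAllele.SB) -> "Genome":
        """Genome of a released drive male for the active variant."""
        if cfg.uses_drive_site:
            return Genome(Ploidy.HAPLOID, (FertilityAllele.WILD,), (social,),
                          (DriveSiteAllele.DRIVE_RESCUE,))
        return Genome(Ploidy.HAPLOID, (FertilityAllele.DRIVE,), (social,))


@dataclass(frozen=True)
class DriveConfig:
    """Drive performance parameters.

    conversion_rate
        Probability that the wild-type allele in a drive/wild-type germline
        is converted to a drive copy (homing).
    germline_res_rate
        Germline resistance allele formation rate.  By default interpreted
        as conditional on the allele *not* being converted, so the net
        resistance rate is ``(1-c) * r_g`` and the total germline cut rate
        is ``c + (1-c) * r_g``; set ``germline_res_absolute=True`` for the
        additive reading (total cut ``c + r_g``) used in total-cut-rate
        parameter sweeps.
    embryo_res_rate
        Probability that each wild-type allele in an offspring of a drive
        mother is mutated to resistance by maternally deposited Cas9.
    somatic_fitness
        Fecundity multiplier for drive/wild-type heterozygous females
        (leaky somatic expression).
    """

    conversion_rate: float = 0.95
    germline_res_rate: float = 0.5
    embryo_res_rate: float = 0.05
    somatic_fitness: float = 0.98
    variant: DriveVariant = DriveVariant.STANDARD
    germline_res_absolute: bool = False

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "germline_res_rate", "embryo_res_rate", "somatic_fitness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if isinstance(self.variant, str) and not isinstance(self.variant, DriveVariant):
            object.__setattr__(self, "variant", DriveVariant(self.variant))

    @property
    def uses_drive_site(self) -> bool:
        return self.variant in _TWO_TARGET

    @property
    def germline_res_net(self) -> float:
        """Probability a targeted germline wild-type allele ends up resistant."""
        if self.germline_res_absolute:
            return min(self.germline_res_rate, 1.0 - self.conversion_rate)
        return (1.0 - self.conversion_rate) * self.germline_res_rate

    @property
    def total_cut_rate(self) -> float:
        return min(1.0, self.conversion_rate + self.germline_res_net)

    @property
    def germline_res_state(self) -> FertilityAllele:
        if self.variant == DriveVariant.DOMINANT_STERILE:
            return FertilityAllele.RES_DOMSTERILE
        return FertilityAllele.RES_NONFUNC


# ---------------------------------------------------------------------------
# germline gametes
# ---------------------------------------------------------------------------

def _require_diploid(g: Genome) -> None:
    if not g.is_diploid:
        raise ValueError("operation requires a diploid genome")


def _conversion_outcomes(cfg: DriveConfig) -> list[tuple[FertilityAllele, float]]:
    """Fate of the single wild-type allele in a drive/wild-type germline."""
    c = cfg.conversion_rate
    r = cfg.germline_res_net
    return [
        (FertilityAllele.DRIVE, c),
        (cfg.germline_res_state, r),
        (FertilityAllele.WILD, 1.0 - c - r),
    ]


def _fertility_marginal(mother: Genome, cfg: DriveConfig) -> dict[FertilityAllele, float]:
    a, b = mother.fertility
    out: dict[FertilityAllele, float] = {}

    def add(allele: FertilityAllele, p: float) -> None:
        if p > 0.0:
            out[allele] = out.get(allele, 0.0) + p

    if cfg.uses_drive_site:
        # Distant-site cutting: drive carriers cut each wild fertility allele
        # at the total germline cut rate; no homing at the distant locus.
        q = cfg.total_cut_rate if DriveSiteAllele.DRIVE_RESCUE in mother.drive_site else 0.0
        for allele in (a, b):
            if allele == FertilityAllele.WILD and q > 0.0:
                add(FertilityAllele.RES_NONFUNC, 0.5 * q)
                add(FertilityAllele.WILD, 0.5 * (1.0 - q))
            else:
                add(allele, 0.5)
        return out

    alleles = {a, b}
    if alleles == {FertilityAllele.DRIVE, FertilityAllele.WILD}:
        add(FertilityAllele.DRIVE, 0.5)
        for allele, p in _conversion_outcomes(cfg):
            add(allele, 0.5 * p)
    else:
        add(a, 0.5)
        add(b, 0.5)
    return out


def _social_marginal(mother: Genome, cfg: DriveConfig) -> dict[SocialAllele, float]:
    a, b = mother.social
    het = {a, b} == {SocialAllele.SB, SocialAllele.Sb}
    if het and mother.carries_drive():
        # Cleave drives convert the targeted social allele with ideal
        # efficiency before segregation, so every gamete carries the product.
        if cfg.variant == DriveVariant.CLEAVE_SB:
            return {SocialAllele.Sb: 1.0}
        if cfg.variant == DriveVariant.CLEAVE_Sb:
            return {SocialAllele.SB: 1.0}
    return {a: 0.5, b: 0.5} if a != b else {a: 1.0}


def _drive_site_marginal(mother: Genome, cfg: DriveConfig) -> dict[DriveSiteAllele, float]:
    a, b = mother.drive_site
    out: dict[DriveSiteAllele, float] = {}

    def add(allele: DriveSiteAllele, p: float) -> None:
        if p > 0.0:
            out[allele] = out.get(allele, 0.0) + p

    if {a, b} == {DriveSiteAllele.DRIVE_RESCUE, DriveSiteAllele.WILD}:
        add(DriveSiteAllele.DRIVE_RESCUE, 0.5)
        c = cfg.conversion_rate
        r = cfg.germline_res_net
        add(DriveSiteAllele.DRIVE_RESCUE, 0.5 * c)
        add(DriveSiteAllele.RES_NONFUNC, 0.5 * r)
        add(DriveSiteAllele.WILD, 0.5 * (1.0 - c - r))
    else:
        add(a, 0.5)
        add(b, 0.5)
    return out


def gamete_distribution(mother: Genome, cfg: DriveConfig) -> dict[Genome, float]:
    """Exact distribution of germline gametes of a diploid mother.

    Loci are unlinked and segregate independently, so the joint distribution
    is the product of the per-locus marginals (germline cutting acts before
    segregation and independently across loci).
    """
    _require_diploid(mother)
    fm = _fertility_marginal(mother, cfg)
    sm = _social_marginal(mother, cfg)
    out: dict[Genome, float] = {}
    if cfg.uses_drive_site:
        dm = _drive_site_marginal(mother, cfg)
        for f, pf in fm.items():
            for s, ps in sm.items():
                for d, pd in dm.items():
                    g = Genome(Ploidy.HAPLOID, (f,), (s,), (d,))
                    out[g] = out.get(g, 0.0) + pf * ps * pd
    else:
        for f, pf in fm.items():
            for s, ps in sm.items():
                g = Genome(Ploidy.HAPLOID, (f,), (s,))
                out[g] = out.get(g, 0.0) + pf * ps
    return out


def female_germline_gamete(mother: Genome, cfg: DriveConfig, rng: np.random.Generator) -> Genome:
    """Sample one germline gamete (drive conversion / resistance applied)."""
    dist = gamete_distribution(mother, cfg)
    gametes = list(dist)
    probs = np.fromiter((dist[g] for g in gametes), dtype=float)
    return gametes[rng.choice(len(gametes), p=probs / probs.sum())]


# ---------------------------------------------------------------------------
# embryo resistance
# ---------------------------------------------------------------------------

def _embryo_targets(cfg: DriveConfig) -> tuple[bool, bool]:
    """(fertility locus targeted, drive site targeted) by maternal Cas9."""
    return True, cfg.uses_drive_site


def apply_embryo_resistance(offspring: Genome, mother: Genome, cfg: DriveConfig,
                            rng: np.random.Generator) -> Genome:
    """Mutate wild-type alleles in the offspring via maternally deposited Cas9.

    Applies to every wild-type allele at each drive-targeted locus (haploid
    sons included), each independently with probability ``embryo_res_rate``,
    only when the mother carries a drive allele.
    """
    _require_diploid(mother)
    if not mother.carries_drive() or cfg.embryo_res_rate <= 0.0:
        return offspring
    re_ = cfg.embryo_res_rate
    fert = tuple(
        cfg.germline_res_state if a == FertilityAllele.WILD and rng.random() < re_ else a
        for a in offspring.fertility
    )
    drive_site = offspring.drive_site
    if cfg.uses_drive_site:
        drive_site = tuple(
            DriveSiteAllele.RES_NONFUNC if a == DriveSiteAllele.WILD and rng.random() < re_ else a
            for a in drive_site
        )
    return replace(offspring, fertility=fert, drive_site=drive_site)


def embryo_haplotype_distribution(h: Genome, cfg: DriveConfig) -> dict[Genome, float]:
    """Exact embryo-resistance outcome distribution for one haploid set.

    Assumes the mother carries a drive; used by the panmictic recursion.
    """
    re_ = cfg.embryo_res_rate
    out: dict[Genome, float] = {h: 1.0}
    if re_ <= 0.0:
        return out

    def expand(current: dict[Genome, float], mutate) -> dict[Genome, float]:
        nxt: dict[Genome, float] = {}
        for g, p in current.items():
            for g2, p2 in mutate(g):
                nxt[g2] = nxt.get(g2, 0.0) + p * p2
        return nxt

    if h.fertility[0] == FertilityAllele.WILD:
        out = expand(out, lambda g: [
            (replace(g, fertility=(cfg.germline_res_state,)), re_),
            (g, 1.0 - re_),
        ])
    if cfg.uses_drive_site and h.drive_site and h.drive_site[0] == DriveSiteAllele.WILD:
        out = expand(out, lambda g: [
            (replace(g, drive_site=(DriveSiteAllele.RES_NONFUNC,)), re_),
            (g, 1.0 - re_),
        ])
    return out


# ---------------------------------------------------------------------------
# phenotype rules
# ---------------------------------------------------------------------------

def is_female_fertile(g: Genome, cfg: DriveConfig) -> bool:
    """A female is fertile iff she retains a functional fertility allele.

    Under the dominant-sterile variant a single RES_DOMSTERILE allele is
    additionally sterilizing.
    """
    _require_diploid(g)
    if cfg.variant == DriveVariant.DOMINANT_STERILE and (
        FertilityAllele.RES_DOMSTERILE in g.fertility
    ):
        return False
    return FertilityAllele.WILD in g.fertility


def is_female_viable(g: Genome, cfg: DriveConfig) -> bool:
    _require_diploid(g)
    if g.social == (SocialAllele.Sb, SocialAllele.Sb):
        return False  # Sb homozygotes are lethal in females
    if cfg.variant == DriveVariant.TWO_TARGET_HAPLOSUFFICIENT:
        return any(a != DriveSiteAllele.RES_NONFUNC for a in g.drive_site)
    if cfg.variant == DriveVariant.TWO_TARGET_HAPLOLETHAL:
        # the rescue copy rescues itself only: any nonfunctional copy kills
        return all(a != DriveSiteAllele.RES_NONFUNC for a in g.drive_site)
    return True


def is_male_viable(g: Genome, cfg: DriveConfig) -> bool:
    """Haploid males need a functional copy of the essential drive-site gene."""
    if g.is_diploid:
        raise ValueError("male genomes are haploid")
    if cfg.uses_drive_site and g.drive_site:
        return g.drive_site[0] != DriveSiteAllele.RES_NONFUNC
    return True


def social_form(g: Genome, cfg: DriveConfig) -> SocialForm:
    _require_diploid(g)
    if SocialAllele.Sb in g.social:
        return SocialForm.POLYGYNE
    if cfg.variant == DriveVariant.POLYGYNE_DRIVE and g.carries_drive():
        return SocialForm.POLYGYNE
    return SocialForm.MONOGYNE


def greenbeard_survives(mother_form: SocialForm, offspring: Genome, cfg: DriveConfig) -> bool:
    """Whether workers in the natal colony let a new queen live.

    Polygyne workers eliminate new queens lacking the greenbeard trait
    (monogyne-form queens); the greenbeard drive rescues drive carriers.
    """
    if mother_form != SocialForm.POLYGYNE:
        return True
    if social_form(offspring, cfg) == SocialForm.POLYGYNE:
        return True
    if cfg.variant == DriveVariant.GREENBEARD_DRIVE and offspring.carries_drive():
        return True
    return False


def fecundity_multiplier(g: Genome, cfg: DriveConfig) -> float:
    """Relative queen output: 0 if sterile, f_s for drive/wild heterozygotes."""
    _require_diploid(g)
    if not is_female_fertile(g, cfg):
        return 0.0
    if cfg.uses_drive_site:
        het = set(g.drive_site) == {DriveSiteAllele.DRIVE_RESCUE, DriveSiteAllele.WILD}
    else:
        het = set(g.fertility) == {FertilityAllele.DRIVE, FertilityAllele.WILD}
    return cfg.somatic_fitness if het else 1.0


def viable_daughter_fraction(queen: Genome, mate: Genome, cfg: DriveConfig,
                             mother_form: SocialForm) -> float:
    """Expected fraction of daughters that are viable and escape the cull.

    Exact enumeration over germline gametes, paternal alleles and embryo
    resistance outcomes; used to validate polygyne replacement candidates
    and to detect colonies that cannot produce any viable daughter.
    """
    drive_mother = queen.carries_drive()
    total = 0.0
    for gm, pm in gamete_distribution(queen, cfg).items():
        mats = embryo_haplotype_distribution(gm, cfg) if drive_mother else {gm: 1.0}
        pats = embryo_haplotype_distribution(mate, cfg) if drive_mother else {mate: 1.0}
        for hm, phm in mats.items():
            for hp, php in pats.items():
                daughter = Genome(
                    Ploidy.DIPLOID,
                    (hm.fertility[0], hp.fertility[0]),
                    (hm.social[0], hp.social[0]),
                    (hm.drive_site[0], hp.drive_site[0]) if cfg.uses_drive_site else (),
                )
                if is_female_viable(daughter, cfg) and greenbeard_survives(
                    mother_form, daughter, cfg
                ):
                    total += pm * phm * php
    return total


# ---------------------------------------------------------------------------
# vectorized kernels (integer-coded allele arrays)
# ---------------------------------------------------------------------------

W = int(FertilityAllele.WILD)
D = int(FertilityAllele.DRIVE)
R = int(FertilityAllele.RES_NONFUNC)
R_DOM = int(FertilityAllele.RES_DOMSTERILE)
SB = int(SocialAllele.SB)
Sb = int(SocialAllele.Sb)
DS_W = int(DriveSiteAllele.WILD)
DS_D = int(DriveSiteAllele.DRIVE_RESCUE)
DS_R = int(DriveSiteAllele.RES_NONFUNC)
NO_ALLELE = -1  # marks an unused drive-site / mate slot


def batch_carries_drive(f1, f2, d1, d2) -> np.ndarray:
    return (f1 == D) | (f2 == D) | (d1 == DS_D) | (d2 == DS_D)


def _batch_convert_pair(a1, a2, drive_code, res_code, wild_code, cfg, rng):
    """Germline homing at the locus where the drive sits (in place on copies)."""
    a1 = a1.copy()
    a2 = a2.copy()
    het12 = (a1 == drive_code) & (a2 == wild_code)
    het21 = (a2 == drive_code) & (a1 == wild_code)
    target_is_2 = het12
    target_any = het12 | het21
    n = a1.shape[0]
    u = rng.random(n)
    c = cfg.conversion_rate
    r = cfg.germline_res_net
    conv = target_any & (u < c)
    res = target_any & ~conv & (u < c + r)
    a2[conv & target_is_2] = drive_code
    a2[res & target_is_2] = res_code
    a1[conv & ~target_is_2] = drive_code
    a1[res & ~target_is_2] = res_code
    return a1, a2


def _batch_pick(a1, a2, rng):
    take2 = rng.random(a1.shape[0]) < 0.5
    return np.where(take2, a2, a1)


def batch_gametes(f1, f2, s1, s2, d1, d2, cfg: DriveConfig, rng: np.random.Generator):
    """Sample one germline gamete per mother; returns (fert, social, drive_site).

    Input arrays are the mothers' diploid allele codes (one row per needed
    gamete; repeat mother rows for multiple offspring).  ``d1``/``d2`` are
    ignored (and NO_ALLELE returned) unless a two-target variant is active.
    """
    n = f1.shape[0]
    res_code = int(cfg.germline_res_state)

    if cfg.uses_drive_site:
        g1, g2 = _batch_convert_pair(d1, d2, DS_D, DS_R, DS_W, cfg, rng)
        gd = _batch_pick(g1, g2, rng)
        carrier = (d1 == DS_D) | (d2 == DS_D)
        q = cfg.total_cut_rate
        a1 = f1.copy()
        a2 = f2.copy()
        for a in (a1, a2):
            cut = carrier & (a == W) & (rng.random(n) < q)
            a[cut] = R
        gf = _batch_pick(a1, a2, rng)
    else:
        a1, a2 = _batch_convert_pair(f1, f2, D, res_code, W, cfg, rng)
        gf = _batch_pick(a1, a2, rng)
        gd = np.full(n, NO_ALLELE, dtype=f1.dtype)

    gs = _batch_pick(s1, s2, rng)
    if cfg.variant in (DriveVariant.CLEAVE_SB, DriveVariant.CLEAVE_Sb):
        carrier = batch_carries_drive(f1, f2, d1, d2)
        het = s1 != s2
        forced = Sb if cfg.variant == DriveVariant.CLEAVE_SB else SB
        gs = np.where(carrier & het, forced, gs)
    return gf, gs, gd


def batch_embryo_resistance(alleles: np.ndarray, mother_has_drive: np.ndarray,
                            cfg: DriveConfig, locus: str, rng: np.random.Generator) -> np.ndarray:
    """Embryo cutting of one allele column; ``locus`` is 'fertility' or 'drive_site'."""
    re_ = cfg.embryo_res_rate
    if re_ <= 0.0:
        return alleles
    out = alleles.copy()
    if locus == "fertility":
        wild, res_code = W, int(cfg.germline_res_state)
    elif locus == "drive_site":
        wild, res_code = DS_W, DS_R
    else:  # pragma: no cover - programming error
        raise ValueError(locus)
    hit = mother_has_drive & (out == wild) & (rng.random(out.shape[0]) < re_)
    out[hit] = res_code
    return out


def batch_female_fertile(f1, f2, cfg: DriveConfig) -> np.ndarray:
    ok = (f1 == W) | (f2 == W)
    if cfg.variant == DriveVariant.DOMINANT_STERILE:
        ok &= (f1 != R_DOM) & (f2 != R_DOM)
    return ok


def batch_female_viable(s1, s2, d1, d2, cfg: DriveConfig) -> np.ndarray:
    ok = ~((s1 == Sb) & (s2 == Sb))
    if cfg.variant == DriveVariant.TWO_TARGET_HAPLOSUFFICIENT:
        ok &= (d1 != DS_R) | (d2 != DS_R)
    elif cfg.variant == DriveVariant.TWO_TARGET_HAPLOLETHAL:
        ok &= (d1 != DS_R) & (d2 != DS_R)
    return ok


def batch_social_form(f1, f2, s1, s2, d1, d2, cfg: DriveConfig) -> np.ndarray:
    poly = (s1 == Sb) | (s2 == Sb)
    if cfg.variant == DriveVariant.POLYGYNE_DRIVE:
        poly |= batch_carries_drive(f1, f2, d1, d2)
    return np.where(poly, int(SocialForm.POLYGYNE), int(SocialForm.MONOGYNE)).astype(np.int8)


def batch_greenbeard_survives(mother_poly: np.ndarray, offspring_form: np.ndarray,
                              f1, f2, d1, d2, cfg: DriveConfig) -> np.ndarray:
    ok = ~mother_poly | (offspring_form == int(SocialForm.POLYGYNE))
    if cfg.variant == DriveVariant.GREENBEARD_DRIVE:
        ok |= batch_carries_drive(f1, f2, d1, d2)
    return ok


def batch_fecundity(f1, f2, d1, d2, cfg: DriveConfig) -> np.ndarray:
    fec = np.where(batch_female_fertile(f1, f2, cfg), 1.0, 0.0)
    if cfg.uses_drive_site:
        het = ((d1 == DS_D) & (d2 == DS_W)) | ((d2 == DS_D) & (d1 == DS_W))
    else:
        het = ((f1 == D) & (f2 == W)) | ((f2 == D) & (f1 == W))
    fec[het & (fec > 0)] = cfg.somatic_fitness
    return fec
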