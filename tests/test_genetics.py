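"""Inheritance rules: exact enumeration oracles, sampling consistency and
phenotype rules for every drive variant."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from solenopsim.genetics import (
    DriveConfig,
    DriveSiteAllele,
    DriveVariant,
    FertilityAllele,
    Genome,
    Ploidy,
    SocialAllele,
    SocialForm,
    apply_embryo_resistance,
    batch_carries_drive,
    batch_embryo_resistance,
    batch_fecundity,
    batch_female_fertile,
    batch_female_viable,
    batch_gametes,
    batch_greenbeard_survives,
    batch_social_form,
    embryo_haplotype_distribution,
    fecundity_multiplier,
    female_germline_gamete,
    gamete_distribution,
    greenbeard_survives,
    is_female_fertile,
    is_female_viable,
    is_male_viable,
    social_form,
    viable_daughter_fraction,
)

from conftest import D, R, SB, Sb, W, diploid, haploid

DSW, DSD, DSR = DriveSiteAllele.WILD, DriveSiteAllele.DRIVE_RESCUE, DriveSiteAllele.RES_NONFUNC
RD = FertilityAllele.RES_DOMSTERILE

ALL_FERT = [W, D, R]


def oracle_fertility_marginal(a, b, cfg):
    """Independent closed-form gamete probabilities at the fertility locus
    for the standard drive: the wild-type allele in a drive/wild germline is
    converted with probability c, mutates with probability (1-c)*r_g, and
    one allele segregates with probability 1/2."""
    c, rg = cfg.conversion_rate, cfg.germline_res_rate
    out = {}
    if {a, b} == {D, W}:
        out[D] = 0.5 + 0.5 * c
        out[cfg.germline_res_state] = 0.5 * (1 - c) * rg
        out[W] = 0.5 * (1 - c) * (1 - rg)
    else:
        for al in (a, b):
            out[al] = out.get(al, 0.0) + 0.5
    return {k: v for k, v in out.items() if v > 0}


@pytest.mark.parametrize("a,b", list(itertools.combinations_with_replacement(ALL_FERT, 2)))
def test_gamete_probabilities_match_enumeration(a, b, default_cfg):
    """All 9 (6 unordered) diploid fertility genotypes reproduce the exact
    closed-form gamete distribution."""
    dist = gamete_distribution(diploid(a, b), default_cfg)
    marg = {}
    for g, p in dist.items():
        marg[g.fertility[0]] = marg.get(g.fertility[0], 0.0) + p
    oracle = oracle_fertility_marginal(a, b, default_cfg)
    assert set(marg) == set(oracle)
    for k in oracle:
        assert marg[k] == pytest.approx(oracle[k], abs=1e-12)
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


def test_default_heterozygote_gamete_probabilities(default_cfg):
    """Default-parameter drive: a drive/wild mother transmits at 0.975."""
    dist = gamete_distribution(diploid(D, W), default_cfg)
    by_fert = {g.fertility[0]: p for g, p in dist.items()}
    assert by_fert[D] == pytest.approx(0.975)
    assert by_fert[R] == pytest.approx(0.0125)
    assert by_fert[W] == pytest.approx(0.0125)


def test_full_conversion_transmits_drive_always():
    cfg = DriveConfig(conversion_rate=1.0, germline_res_rate=0.0, embryo_res_rate=0.0)
    dist = gamete_distribution(diploid(D, W), cfg)
    assert {g.fertility[0] for g in dist} == {D}


def test_wild_mother_gametes_are_wild(default_cfg):
    dist = gamete_distribution(diploid(W, W), default_cfg)
    assert {g.fertility[0] for g in dist} == {W}


def test_germline_gamete_requires_diploid(default_cfg, rng):
    with pytest.raises(ValueError):
        female_germline_gamete(haploid(W), default_cfg, rng)


def test_monte_carlo_gametes_match_closed_form(default_cfg, rng):
    """Sampled gamete frequencies agree with enumeration within 3 SE."""
    mother = diploid(D, W)
    n = 100_000
    counts = {}
    for _ in range(n):
        g = female_germline_gamete(mother, default_cfg, rng)
        counts[g.fertility[0]] = counts.get(g.fertility[0], 0) + 1
    for allele, p in {D: 0.975, R: 0.0125, W: 0.0125}.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts.get(allele, 0) / n - p) < 3 * se


@pytest.mark.parametrize("variant", list(DriveVariant))
def test_gamete_distribution_normalized_all_variants(variant):
    cfg = DriveConfig(variant=variant)
    fert_pool = [W, D, RD] if variant == DriveVariant.DOMINANT_STERILE else ALL_FERT
    ds_pool = [DSW, DSD, DSR] if cfg.uses_drive_site else [None]
    for f1, f2 in itertools.combinations_with_replacement(fert_pool, 2):
        for s1, s2 in itertools.combinations_with_replacement([SB, Sb], 2):
            for d1 in ds_pool:
                g = diploid(f1, f2, s1, s2, (d1, d1) if d1 is not None else None)
                dist = gamete_distribution(g, cfg)
                assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


@given(c=st.floats(0, 1), rg=st.floats(0, 1), re=st.floats(0, 1))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_gamete_distribution_normalized_random_rates(c, rg, re):
    cfg = DriveConfig(conversion_rate=c, germline_res_rate=rg, embryo_res_rate=re)
    for mother in (diploid(D, W), diploid(D, R), diploid(W, R, SB, Sb)):
        assert sum(gamete_distribution(mother, cfg).values()) == pytest.approx(1.0)


# -- embryo resistance -----------------------------------------------------

def test_embryo_resistance_needs_drive_mother(default_cfg, rng):
    off = diploid(W, W)
    assert apply_embryo_resistance(off, diploid(W, R), default_cfg, rng) == off


def test_embryo_resistance_rate_is_per_allele(default_cfg):
    dist = embryo_haplotype_distribution(haploid(W), default_cfg)
    assert dist[haploid(R)] == pytest.approx(0.05)
    assert dist[haploid(W)] == pytest.approx(0.95)


def test_embryo_resistance_forced_limit(rng):
    cfg = DriveConfig(embryo_res_rate=1.0)
    out = apply_embryo_resistance(diploid(W, W), diploid(D, W), cfg, rng)
    assert out.fertility == (R, R)


# -- fertility / viability / social form ------------------------------------

@pytest.mark.parametrize("genome,fertile", [
    (diploid(D, D), False),
    (diploid(W, W), True),
    (diploid(W, D), True),
    (diploid(D, R), False),
    (diploid(W, R), True),
])
def test_female_fertility_standard(genome, fertile, default_cfg):
    assert is_female_fertile(genome, default_cfg) is fertile


def test_dominant_sterile_resistance_sterilizes():
    cfg = DriveConfig(variant=DriveVariant.DOMINANT_STERILE)
    assert not is_female_fertile(diploid(D, RD), cfg)
    assert not is_female_fertile(diploid(W, RD), cfg)
    assert is_female_fertile(diploid(W, D), cfg)


def test_sb_homozygotes_are_lethal(default_cfg):
    assert not is_female_viable(diploid(W, W, Sb, Sb), default_cfg)
    assert is_female_viable(diploid(W, W, SB, Sb), default_cfg)


def test_two_target_viability_rules():
    hs = DriveConfig(variant=DriveVariant.TWO_TARGET_HAPLOSUFFICIENT)
    hl = DriveConfig(variant=DriveVariant.TWO_TARGET_HAPLOLETHAL)
    g_dr = diploid(W, W, ds=(DSD, DSR))
    g_rr = diploid(W, W, ds=(DSR, DSR))
    assert is_female_viable(g_dr, hs)       # one functional copy suffices
    assert not is_female_viable(g_rr, hs)
    assert not is_female_viable(g_dr, hl)   # rescue rescues itself only
    assert not is_male_viable(haploid(W, d=DSR), hs)
    assert is_male_viable(haploid(W, d=DSD), hl)


@pytest.mark.parametrize("genome,cfgkw,form", [
    (diploid(W, W, SB, SB), {}, SocialForm.MONOGYNE),
    (diploid(W, W, SB, Sb), {}, SocialForm.POLYGYNE),
    (diploid(D, W, SB, SB), {"variant": DriveVariant.POLYGYNE_DRIVE}, SocialForm.POLYGYNE),
    (diploid(W, W, SB, SB), {"variant": DriveVariant.POLYGYNE_DRIVE}, SocialForm.MONOGYNE),
])
def test_social_form(genome, cfgkw, form):
    assert social_form(genome, DriveConfig(**cfgkw)) == form


def test_greenbeard_cull_rules(default_cfg):
    gb = DriveConfig(variant=DriveVariant.GREENBEARD_DRIVE)
    sb_homo = diploid(W, W, SB, SB)
    assert not greenbeard_survives(SocialForm.POLYGYNE, sb_homo, default_cfg)
    assert greenbeard_survives(SocialForm.MONOGYNE, sb_homo, default_cfg)
    assert greenbeard_survives(SocialForm.POLYGYNE, diploid(D, W, SB, SB), gb)
    assert greenbeard_survives(SocialForm.POLYGYNE, diploid(W, W, SB, Sb), default_cfg)


def test_polygyne_drive_carriers_not_culled():
    """A polygyne-form drive carrier is accepted by polygyne workers even
    without an Sb allele (the drive itself confers the greenbeard trait)."""
    cfg = DriveConfig(variant=DriveVariant.POLYGYNE_DRIVE)
    assert greenbeard_survives(SocialForm.POLYGYNE, diploid(D, W, SB, SB), cfg)


@pytest.mark.parametrize("genome,expected", [
    (diploid(D, W), 0.98),
    (diploid(W, W), 1.0),
    (diploid(D, D), 0.0),
    (diploid(W, R), 1.0),
])
def test_fecundity_multiplier(genome, expected, default_cfg):
    assert fecundity_multiplier(genome, default_cfg) == pytest.approx(expected)


def test_cleave_sb_mother_gametes_never_carry_sb():
    """With ideal cleave efficiency an SB/Sb drive mother transmits no Sb."""
    cfg = DriveConfig(variant=DriveVariant.CLEAVE_Sb)
    dist = gamete_distribution(diploid(D, W, SB, Sb), cfg)
    assert all(g.social[0] == SB for g in dist)
    cfg2 = DriveConfig(variant=DriveVariant.CLEAVE_SB)
    dist2 = gamete_distribution(diploid(D, W, SB, Sb), cfg2)
    assert all(g.social[0] == Sb for g in dist2)


def test_cleave_sb_queen_with_sb_mate_has_no_viable_daughters():
    cfg = DriveConfig(variant=DriveVariant.CLEAVE_SB)
    frac = viable_daughter_fraction(
        diploid(D, W, SB, Sb), haploid(W, Sb), cfg, SocialForm.POLYGYNE)
    assert frac == 0.0  # every daughter is an Sb homozygote


def test_germline_resistance_interpretations():
    conditional = DriveConfig(conversion_rate=0.8, germline_res_rate=0.5)
    absolute = DriveConfig(conversion_rate=0.8, germline_res_rate=0.5,
                           germline_res_absolute=True)
    assert conditional.germline_res_net == pytest.approx(0.1)
    assert conditional.total_cut_rate == pytest.approx(0.9)
    assert absolute.germline_res_net == pytest.approx(0.2)  # capped at 1-c
    assert absolute.total_cut_rate == pytest.approx(1.0)


# -- vectorized kernels vs the enumeration ----------------------------------

@pytest.mark.parametrize("variant", [
    DriveVariant.STANDARD, DriveVariant.DOMINANT_STERILE,
    DriveVariant.TWO_TARGET_HAPLOLETHAL, DriveVariant.CLEAVE_Sb,
])
def test_batch_gametes_match_enumeration(variant, rng):
    """The engine's vectorized gamete kernel reproduces the exact per-locus
    distribution of the scalar enumeration (4 SE at n=40000)."""
    cfg = DriveConfig(variant=variant)
    ds = (DSD, DSW) if cfg.uses_drive_site else None
    fert = (W, W) if cfg.uses_drive_site else (D, W)
    mother = diploid(*fert, SB, Sb, ds)
    dist = gamete_distribution(mother, cfg)

    n = 40_000
    rep = lambda v: np.full(n, int(v), dtype=np.int8)
    d1, d2 = (rep(ds[0]), rep(ds[1])) if ds else (rep(-1), rep(-1))
    gf, gs, gd = batch_gametes(rep(mother.fertility[0]), rep(mother.fertility[1]),
                               rep(SB), rep(Sb), d1, d2, cfg, rng)
    for key_fn, col in [
        (lambda g: int(g.fertility[0]), gf),
        (lambda g: int(g.social[0]), gs),
    ] + ([(lambda g: int(g.drive_site[0]), gd)] if cfg.uses_drive_site else []):
        marg = {}
        for g, p in dist.items():
            marg[key_fn(g)] = marg.get(key_fn(g), 0.0) + p
        for code, p in marg.items():
            se = max(np.sqrt(p * (1 - p) / n), 1e-9)
            assert abs((col == code).mean() - p) < 4 * se + 1e-12


def test_batch_phenotypes_match_scalar(rng):
    """Boolean kernels agree with the scalar rules row by row."""
    cfg = DriveConfig(variant=DriveVariant.DOMINANT_STERILE)
    pool = [W, D, RD]
    rows = list(itertools.product(pool, pool, [SB, Sb], [SB, Sb]))
    f1 = np.array([int(r[0]) for r in rows], dtype=np.int8)
    f2 = np.array([int(r[1]) for r in rows], dtype=np.int8)
    s1 = np.array([int(r[2]) for r in rows], dtype=np.int8)
    s2 = np.array([int(r[3]) for r in rows], dtype=np.int8)
    no = np.full(len(rows), -1, dtype=np.int8)
    fert = batch_female_fertile(f1, f2, cfg)
    viab = batch_female_viable(s1, s2, no, no, cfg)
    fec = batch_fecundity(f1, f2, no, no, cfg)
    form = batch_social_form(f1, f2, s1, s2, no, no, cfg)
    for i, (a, b, sa, sb_) in enumerate(rows):
        g = diploid(a, b, sa, sb_)
        assert fert[i] == is_female_fertile(g, cfg)
        assert viab[i] == is_female_viable(g, cfg)
        assert fec[i] == pytest.approx(fecundity_multiplier(g, cfg))
        assert form[i] == int(social_form(g, cfg))


def test_batch_embryo_resistance_rate(rng):
    cfg = DriveConfig(embryo_res_rate=0.05)
    n = 200_000
    alleles = np.full(n, int(W), dtype=np.int8)
    drive = np.ones(n, dtype=bool)
    out = batch_embryo_resistance(alleles, drive, cfg, "fertility", rng)
    frac = (out == int(R)).mean()
    assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / n)
    nodrive = batch_embryo_resistance(alleles, ~drive, cfg, "fertility", rng)
    assert (nodrive == int(W)).all()
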