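"""Deterministic panmictic haplodiploid recursion and genetic load."""

import numpy as np
import pytest

from solenopsim.genetics import DriveConfig, DriveVariant, FertilityAllele, Genome, Ploidy, SocialAllele
from solenopsim.panmictic import (
    GenotypeFrequencies,
    PanmicticExtinction,
    PanmicticModel,
    equilibrium_genetic_load,
    load_sweep,
    next_generation,
    required_genetic_load,
)

from conftest import D, R, SB, W, diploid, haploid


def _female_index(model, fert_alleles: set) -> int:
    """Index of the female genotype with the given unordered fertility pair."""
    for i, g in enumerate(model.female_genotypes):
        if set(g.fertility) == fert_alleles and len(g.fertility) == 2:
            if len(fert_alleles) == 2 or g.fertility[0] == g.fertility[1]:
                return i
    raise KeyError(fert_alleles)


def test_all_wild_is_a_fixed_point(default_cfg):
    m = PanmicticModel(default_cfg)
    state = m.wild_state()
    nxt = m.next_generation(state)
    assert np.allclose(nxt.females, state.females, atol=1e-14)
    assert np.allclose(nxt.males, state.males, atol=1e-14)
    assert m.genetic_load(state) == pytest.approx(0.0, abs=1e-12)


def test_full_conversion_cross():
    """c=1, no resistance: a drive/wild mother crossed to wild males gives
    only drive/wild daughters and only drive sons."""
    cfg = DriveConfig(conversion_rate=1.0, germline_res_rate=0.0,
                      embryo_res_rate=0.0, somatic_fitness=1.0)
    m = PanmicticModel(cfg)
    dw = _female_index(m, {D, W})
    F = np.zeros(len(m.female_genotypes))
    M = np.zeros(len(m.haplotypes))
    F[dw] = 1.0
    M[m.haplotypes.index(haploid(W))] = 1.0
    nxt = m.next_generation(GenotypeFrequencies(F, M))
    assert nxt.females[dw] == pytest.approx(1.0)
    assert nxt.males[m.haplotypes.index(haploid(D))] == pytest.approx(1.0)


def test_frequencies_stay_normalized(default_cfg):
    m = PanmicticModel(default_cfg)
    state = m.introduce_drive_males(m.wild_state(), 0.01)
    for _ in range(1000):
        state = m.next_generation(state)
        assert state.females.sum() == pytest.approx(1.0, abs=1e-9)
        assert state.males.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(state.females >= -1e-15)


def test_next_generation_module_wrapper(default_cfg):
    m = PanmicticModel(default_cfg)
    s = m.introduce_drive_males(m.wild_state(), 0.01)
    a = next_generation(s, default_cfg)
    b = m.next_generation(s)
    assert np.allclose(a.females, b.females)


def test_required_genetic_load_values():
    assert required_genetic_load(6) == pytest.approx(1 - 1 / 6)
    assert round(required_genetic_load(6), 2) == 0.83
    assert required_genetic_load(2) == pytest.approx(0.5)
    assert required_genetic_load(10) == pytest.approx(0.9)
    with pytest.raises(ValueError):
        required_genetic_load(1.0)


def test_null_drive_has_no_load():
    cfg = DriveConfig(conversion_rate=0.0, germline_res_rate=0.0,
                      embryo_res_rate=0.0, somatic_fitness=1.0)
    res = equilibrium_genetic_load(cfg, max_gens=2000)
    assert res.load == pytest.approx(0.0, abs=1e-6)


def test_perfect_drive_eliminates():
    cfg = DriveConfig(conversion_rate=1.0, germline_res_rate=0.0,
                      embryo_res_rate=0.0, somatic_fitness=1.0)
    res = equilibrium_genetic_load(cfg)
    assert res.load == pytest.approx(1.0, abs=1e-6)


def test_costly_non_driving_transgene_is_lost():
    cfg = DriveConfig(conversion_rate=0.0, germline_res_rate=0.0,
                      embryo_res_rate=0.0, somatic_fitness=0.9)
    res = equilibrium_genetic_load(cfg)
    assert res.drive_lost


def test_load_monotone_in_conversion():
    loads = [equilibrium_genetic_load(DriveConfig(conversion_rate=c)).load
             for c in (0.7, 0.8, 0.9, 0.99)]
    assert all(b > a for a, b in zip(loads, loads[1:]))


def test_dominant_sterile_beats_standard_at_low_conversion():
    kw = dict(conversion_rate=0.8, germline_res_rate=0.2)
    ds = equilibrium_genetic_load(DriveConfig(variant=DriveVariant.DOMINANT_STERILE, **kw))
    st = equilibrium_genetic_load(DriveConfig(**kw))
    assert ds.load > st.load


def test_dominant_sterile_high_cut_low_conversion():
    """With the total cut rate near 1, dominant-sterile resistance delivers
    near-maximal load even at low drive conversion."""
    low_c = equilibrium_genetic_load(DriveConfig(
        conversion_rate=0.3, germline_res_rate=1.0,
        variant=DriveVariant.DOMINANT_STERILE))
    high_c = equilibrium_genetic_load(DriveConfig(
        conversion_rate=0.95, germline_res_rate=1.0,
        variant=DriveVariant.DOMINANT_STERILE))
    assert low_c.load > 0.95
    assert low_c.load == pytest.approx(high_c.load, abs=0.02)


def test_two_target_haplolethal_equals_dominant_sterile_at_full_cut():
    """At 100% total cutting the haplolethal distant-site design and the
    dominant-sterile design produce the same equilibrium genetic load."""
    kw = dict(conversion_rate=0.6, germline_res_rate=1.0)
    hl = equilibrium_genetic_load(DriveConfig(
        variant=DriveVariant.TWO_TARGET_HAPLOLETHAL, **kw))
    ds = equilibrium_genetic_load(DriveConfig(
        variant=DriveVariant.DOMINANT_STERILE, **kw))
    assert hl.load == pytest.approx(ds.load, abs=1e-4)


def test_two_target_haplosufficient_optimum_below_full_cut():
    """For the haplosufficient drive-site design, 100% cutting accumulates
    nonfunctional rescue-site alleles and lowers the load."""
    full = equilibrium_genetic_load(DriveConfig(
        conversion_rate=0.6, germline_res_rate=1.0,
        variant=DriveVariant.TWO_TARGET_HAPLOSUFFICIENT))
    partial = equilibrium_genetic_load(DriveConfig(
        conversion_rate=0.6, germline_res_rate=0.5,
        variant=DriveVariant.TWO_TARGET_HAPLOSUFFICIENT))
    assert partial.load > full.load


def test_extinction_is_signalled(default_cfg):
    m = PanmicticModel(default_cfg)
    F = np.zeros(len(m.female_genotypes))
    F[m.female_genotypes.index(diploid(D, D))] = 1.0  # all females sterile
    M = np.zeros(len(m.haplotypes))
    M[m.haplotypes.index(haploid(D))] = 1.0
    with pytest.raises(PanmicticExtinction):
        m.next_generation(GenotypeFrequencies(F, M))


def test_recursion_matches_stochastic_simulation(default_cfg, rng):
    """Independent oracle: a 100k-individual stochastic haplodiploid
    simulation written directly from the inheritance rules tracks the
    deterministic recursion within 3 binomial standard errors."""
    c, rg, re_, fs = 0.95, 0.5, 0.05, 0.98
    N = 100_000
    fem = np.zeros((N, 2), dtype=np.int8)
    mal = np.zeros(N, dtype=np.int8)
    mal[: N // 100] = 1

    def gamete(femarr):
        n = len(femarr)
        a1, a2 = femarr[:, 0].copy(), femarr[:, 1].copy()
        dw = ((a1 == 1) & (a2 == 0)) | ((a1 == 0) & (a2 == 1))
        u = rng.random(n)
        conv = dw & (u < c)
        res = dw & ~conv & (u < c + (1 - c) * rg)
        w1 = a1 == 0
        a1 = np.where(conv & w1, 1, a1)
        a1 = np.where(res & w1, 2, a1)
        a2 = np.where(conv & ~w1, 1, a2)
        a2 = np.where(res & ~w1, 2, a2)
        return np.where(rng.random(n) < 0.5, a2, a1)

    gens = 25
    for _ in range(gens):
        fertile = (fem[:, 0] == 0) | (fem[:, 1] == 0)
        het = ((fem[:, 0] == 1) & (fem[:, 1] == 0)) | ((fem[:, 0] == 0) & (fem[:, 1] == 1))
        fec = np.where(fertile, np.where(het, fs, 1.0), 0.0)
        moms = rng.choice(N, size=2 * N, p=fec / fec.sum())
        momg = fem[moms]
        g = gamete(momg)
        hasD = (momg[:, 0] == 1) | (momg[:, 1] == 1)
        g = np.where(hasD & (g == 0) & (rng.random(2 * N) < re_), 2, g)
        pat = mal[rng.integers(0, N, N)].copy()
        pat = np.where(hasD[:N] & (pat == 0) & (rng.random(N) < re_), 2, pat)
        fem = np.column_stack([g[:N], pat])
        mal = g[N:]

    m = PanmicticModel(default_cfg)
    state = m.introduce_drive_males(m.wild_state(), 0.01)
    for _ in range(gens):
        state = m.next_generation(state)
    expected_male_d = float(state.males[m.haplotypes.index(haploid(D))])
    observed = (mal == 1).mean()
    se = np.sqrt(expected_male_d * (1 - expected_male_d) / N)
    # drift accumulates over generations; allow a small multiple of the SE
    assert abs(observed - expected_male_d) < max(10 * se, 0.01)


def test_load_sweep_grid():
    grid = load_sweep([0.8, 0.9, 1.0], [0.5], DriveConfig())
    assert len(grid) == 3
    assert grid.genetic_load.is_monotonic_increasing
    assert set(grid.columns) >= {"conversion_rate", "germline_res_rate", "genetic_load"}
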