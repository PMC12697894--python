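# solenopsim

Colony-level modeling of CRISPR homing suppression gene drive in the
invasive fire ant *Solenopsis invicta*.

Fire ants are haplodiploid (diploid queens, haploid males) and live in two
social forms — single-queen (monogyne) colonies and multi-queen (polygyne)
colonies governed by the *SB/Sb* greenbeard supergene (*Sb* is dominant
polygyne; *Sb/Sb* females die; polygyne workers cull queens lacking *Sb*).
Both features complicate suppression gene drives: drive-sterilized females
never found colonies, and the two social forms differ sharply in
generation time, dispersal and competition. `solenopsim` is for
quantitative geneticists and invasion ecologists who want to ask whether,
and how fast, a homing drive disrupting a female-fertility gene can
suppress such a population.

The package provides:

* a **spatially explicit stochastic simulator** of individual colonies on
  a 1.85 km square arena — logistic colony growth, distance-decaying
  competition kernels, density-dependent establishment and survival,
  biomass-weighted local mate choice, polygyne representative-queen
  turnover, drive-male releases, native competitor species and invasion
  fronts;
* a **deterministic discrete-generation panmictic haplodiploid model**
  for equilibrium genetic load (suppressive power) and elimination
  thresholds;
* five improved drive variants beyond the standard homing suppression
  drive: dominant-sterile resistance, two-target (haplosufficient or
  haplolethal rescue site), polygyne drive, greenbeard drive, and
  cleave-*SB*/*Sb* drives.

The core genetics: in a drive/wild-type queen's germline the wild-type
allele is converted with probability *c* (0.95 default) or becomes a
nonfunctional resistance allele with probability *r_g* conditional on
non-conversion (0.5); maternal Cas9 converts offspring wild-type alleles
at the embryo rate *r_e* (0.05); drive heterozygous females have relative
fecundity *f_s* (0.98). Drive-homozygous and resistance-homozygous
females are sterile. The **genetic load** L of a drive is the fractional
reduction of per-female viable reproductive output at equilibrium; a
deterministic population with low-density growth rate *g* is eliminated
when L > 1 − 1/g.

## Worked example

Genetic load of the default drive and the elimination threshold:

```bash
$ solenopsim panmictic
equilibrium genetic load: 0.8987 (drive frequency 0.9190, 67 generations)
elimination threshold at growth rate 6: 0.8333

$ solenopsim panmictic --generation-time
monogyne generation time: 4.77 years
polygyne effective generation time: 2.00 years
```

The default drive's equilibrium load (0.90) exceeds the deterministic
elimination threshold for a population with low-density growth rate 6
(0.83), so suppression is expected to be a matter of time scale rather
than power; the monogyne generation time of ~4.8 years is what makes that
time scale long, while polygyne colonies (whose representative queen
genotype turns over every ~2 years) respond much faster.

A small spatial run (a density-preserving 2% fixture of the mixed
monogyne + polygyne arena, default drive released as 15% males for six
years):

```bash
$ solenopsim simulate --scenario mixed --years 40 --seed 1 --scale 0.02 --out demo
replicate 0: year_limit at year 40; final fire biomass fraction 0.619
```

i.e. after 40 years the drive has removed ~38% of fire-ant biomass;
`demo_rep0.csv` holds the yearly time series (counts and biomass by
social form, drive/resistance/*Sb* allele frequencies, nearest-neighbor
index, slice biomass profiles) and `demo.config.json` the exact resolved
configuration for bit-identical replay.

Library use mirrors the CLI:

```python
from solenopsim import DriveConfig, RunConfig, Simulation, make_fixture
from solenopsim import equilibrium_genetic_load

load = equilibrium_genetic_load(DriveConfig(conversion_rate=0.8)).load
cfg = make_fixture(RunConfig.for_scenario("mixed", conversion_rate=1.0,
                                          somatic_fitness=1.0), 0.04)
result = Simulation(cfg, seed=7).run()
print(load, result.years_to_reduction(0.9))
```

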