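# Methods

`solenopsim` models CRISPR homing suppression gene drive in invasive fire
ants (*Solenopsis invicta*) at the level of whole colonies. It has two
components: a spatially explicit stochastic simulator of individual
colonies on a square arena, and a deterministic discrete-generation
panmictic haplodiploid recursion used for genetic-load and
suppression-threshold calculations.

## Drive genetics

Fire ants are haplodiploid: queens are diploid, males are haploid and
develop from unfertilized eggs. The modelled drive is a homing construct
disrupting a haplosufficient female-fertility gene. In the germline of a
drive/wild-type queen the wild-type allele is converted to a drive copy
with probability *c* (default 0.95); if conversion fails it becomes a
nonfunctional resistance allele with probability *r_g* (default 0.5,
interpreted as conditional on non-conversion, so the net resistance rate
is (1−c)·r_g and the total germline cut rate c+(1−c)·r_g — the only
reading under which c and r_g can both take their default values; a
configuration switch `germline_res_absolute` provides the additive
reading used in total-cut-rate sweeps). Maternally deposited Cas9 converts
each wild-type allele in an offspring of a drive-carrying mother with
probability *r_e* (default 0.05), in sons as well as daughters. Females
without a functional fertility allele are sterile; drive/wild-type
heterozygotes have relative fecundity *f_s* (default 0.98). The drive has
no activity in haploid males and carries no male fitness cost.

A second, independently segregating locus carries the social supergene:
*Sb* is dominant polygyne and *Sb/Sb* females die. Polygyne workers cull
new queens that lack the greenbeard trait (monogyne-form queens), so wild
polygyne colonies lose half their daughters and only produce *SB/Sb*
queens.

Variants: **dominant-sterile resistance** makes every resistance allele
dominantly female-sterilizing; **two-target** drives sit at an essential
gene (haplosufficient or haplolethal) that the drive itself rescues, with
extra gRNAs cutting the distant fertility gene at the total cut rate (no
homing there); **polygyne drive** makes every drive carrier develop as a
polygyne colony; **greenbeard drive** rescues *SB/SB* drive carriers from
the worker cull; **cleave-SB / cleave-Sb** convert the targeted social
allele in the germline of drive-carrying heterozygotes with ideal
efficiency. Under the polygyne drive, drive-carrying *SB/SB* daughters of
polygyne colonies are treated as greenbeard-bearing (not culled), since
the drive itself confers the polygyne phenotype. Haploid males with a
nonfunctional copy of the essential two-target gene are nonviable.

All inheritance rules exist twice: as exact per-genotype probability
enumerations (used by the panmictic recursion and as test oracles) and as
vectorized numpy kernels (used by the spatial engine). Property tests pin
the kernels to the enumerations.

## Colony demography

Each colony is one agent: a queen genotype, her stored mate genotype, a
position, an age, a social form and a species. Colony size follows a
logistic curve in age, S(t) = 170000 / (1 + 66 e^(−1.3 t)) workers for
monogyne (and native) colonies and twice that ceiling for polygyne
colonies. Queen production, competition and survival all use the
*monogyne-equivalent* size (polygyne colonies hold more but smaller
workers). A colony of age ≥ 2 produces Poisson-distributed new queens
with mean max(0, (S(t)−10000)/10800) × fecundity × 0.95; the 0.95 factor
is the published implementation calibration for holding carrying capacity
in spatial runs and is retained at its published value (see
*Carrying-capacity census* below). Sterile new queens cannot raise
workers and never found colonies; nonviable and greenbeard-culled
genotypes are removed at the same point.

New queens disperse from their natal colony by independent per-axis
Gaussian displacements whose scale is set so the *mean Euclidean*
displacement equals the configured average dispersal distance (100 m
default; half for polygyne budding; 138.75 m in the invasion scenario);
positions outside the arena are fully redrawn. Age-1 queens take up to 10
attempts to draw a mate from colonies within twice their dispersal sigma
(nearest-50 fallback), weighted by father-colony biomass × queen fecundity
× a polygyne male rate (0.837352526) that offsets the higher polygyne
biomass; monogyne queens reject *Sb*-bearing males and retry. A male is a
fresh germline gamete of the father colony's queen with her embryo-
resistance activity applied. Queens failing all attempts are removed.

Polygyne colonies refresh their representative reproductive queen
genotype: each year, with probability 0.5, a colony attempts to install a
newly mated queen (a daughter of a nearby producing polygyne colony,
mated through the standard rules, required to be viable, fertile,
greenbeard-bearing and capable of producing at least some viable
daughters). An attempt that finds no such candidate kills the colony with
probability 0.8; years without an attempt retain the old genotype. In an
intact population replacement virtually always succeeds, so this
mechanism only shortens colony lifespan once the drive makes fertile
polygyne queens scarce. (The alternative reading — applying the 80%
mortality to every non-replacement year — gives polygyne colonies a
lifetime reproduction far below one at any competition level and is
demographically impossible.)

Monogyne and native colonies die with probability 0.5 at age 6 and always
by age 7 (after that year's reproduction); polygyne colonies are capped
at 70 years.

## Competition and survival

A source colony of age t exerts competition within radius
r_t = 2·sqrt(A_t/π), where A_t = 100 m² × S(t)/170000 is its territory,
declining linearly with distance: contribution S_eff · (1 − d/r_t).
Polygyne sources exert 1.2 × S(t) (twice the workers at 0.6 mass) except
on other polygyne colonies, where a 1/1.2 coefficient cancels the excess.
Cross-species pressure is multiplied by an interspecies factor f ∈ [0,1]
(asymmetric in the invasion scenario: only native-on-fire pressure is
halved). Age-0 colonies receive but do not exert competition.

The competition ratio R is incoming pressure divided by the expected
pressure in an equilibrium population at capacity,
E = Σ_{t=2..7} S_eff(t) · (N p_t / A) · π r_t² / 3, with p_t the
stationary age proportions obtained from the R = 1 survival schedule (the
printed form of this normalization omits p_t and the arena-area division,
which are required dimensionally and appear in the two-species variant).
Establishment survival of age-0 colonies is 0.1·g / ((g−1)R + 1), with g
the low-density growth rate (default 6). Older colonies survive with
probability L − 0.6714·exp(−(2.2221/100000)·S(t)/R), L = 0.95 for
monogyne and native colonies and 0.90 for polygyne. This parsing of the
survival curve is validated by an exact identity: at R = 1 the implied
life table gives a lifetime queen production of 0.9991 ≈ 1 once the 0.95
offspring calibration is removed, which is precisely the calibration
property the published model states. Survival-relevant sizes and radii
are table-lookups by age; neighbor sums use a k-d tree and are verified
exactly against a brute-force all-pairs oracle.

## Yearly cycle and scenarios

Each year: (1) ages increment; (2) colonies of age ≥ 2 reproduce
(gametes, embryo resistance, viability/sterility/greenbeard filters,
dispersal); (3) polygyne queen replacement; (4) age-1 queens mate,
with released drive males available during release years — a mating
attempt draws a released male with probability 0.15/1.15, matching a
release of drive males equal to 15% of the wild male pool, half of them
carrying *Sb*; (5) competition ratios; (6) survival (establishment for
age 0, density plus age-related death otherwise); (7) metrics. Releases
repeat for six years from year 1 (in the invasion scenario, from the
year the fire-ant share of biomass in the left half of slice 7 of ten
vertical slices first reaches 50%). Runs terminate at the year limit, at
fire-ant elimination, or when the drive is lost after the release window.

Scenarios: monogyne-only (capacity 100000 colonies on a 1.85 km square),
polygyne-only, mixed (50000 + 30941 colonies, each form at half its
pure-form density), native coexistence (symmetric interspecies
competition, capacities 50000/30941/50000 and cross terms in the expected
competition), and invasion (fire ants start in the left 40% of the arena,
polygyne behind monogyne, natives filling the rest at full capacity with
asymmetric competition).

Reported metrics per year: colony counts by form and species (the
*established* count, age ≥ 2, matches the initialization bookkeeping; an
age ≥ 1 count is also recorded), biomass in monogyne-worker-equivalent
units (Σ size × mass factor over colonies of age ≥ 1; mass factor 1.0
monogyne/native, 0.6 polygyne), drive/resistance/*Sb* allele frequencies
counted over queen genomes plus stored mates, the Clark–Evans
nearest-neighbor index, and ten-slice biomass profiles.

## Panmictic model, genetic load and generation times

The discrete-generation recursion tracks exact genotype frequencies of
diploid females and haploid males at the active loci. Fecundity-weighted
fertile females are crossed with frequency-weighted males; daughters
combine a maternal germline gamete with the paternal allele set, sons are
unfertilized maternal gametes; embryo resistance applies to offspring of
drive mothers; nonviable genotypes are removed and frequencies
renormalized. The per-configuration transition tensor is precomputed, so
a generation is two tensor contractions. Genetic load is one minus the
per-female production of viable daughters (fecundity-weighted) relative
to the all-wild population; iteration starts from a 1% drive-male
introduction and stops when frequencies change by less than 1e−9 (with
period-2 cycle detection), flagging drive loss. The deterministic
elimination threshold is 1 − 1/g. A cross-check pins the recursion to an
independently written 100000-individual stochastic simulation.

Generation times come from the equilibrium life table at R = 1:
survivorship uses the age-0 establishment rate, the density survival
curve, the 50% age-6 cull and the age-7 cap, in the simulation's
reproduce-before-mortality order; fecundities are the queen-production
means. The mean mother age is Σ t·l_t·m_t / Σ l_t·m_t ≈ 4.8 years for
monogyne colonies. The published figure is 5.4 years; under this life
table the mean mother age cannot exceed ≈ 5.0 even with survival forced
to 1 at every age, so the published figure must rest on a different
(unstated) timing convention — the discrepancy is reported, not
calibrated away. The polygyne effective generation time uses the
representative-genotype turnover (retention (1−p) per year), ≈ 2 years
at the default 50% replacement.

## Numerical and design choices

* Integer-coded allele arrays (int8) and a single `numpy` PCG64 stream
  per replicate; replicate seeds derive from (base seed, replicate
  index). Identical seed and configuration reproduce runs bit-for-bit.
* Mate sampling uses global-weight rejection sampling restricted to the
  search radius, which is exactly the radius-local weighted distribution;
  rare stragglers fall back to explicit local enumeration.
* Scaled fixtures multiply arena *area* and every capacity/initial count
  by the scale, leaving all distances unchanged, so densities, competition
  ratios and per-capita rates are preserved. Tests and the acceptance
  script use a 4% fixture (2000-colony monogyne capacity per half arena).
* Degenerate cases: an empty fertile-female pool raises a signalled
  extinction in the recursion; empty populations yield NaN frequencies;
  competition ratios are floored at 1e−12 before the survival exponent.

## Known limitations and calibration caveats

* **Carrying-capacity census.** With every published constant at its
  printed value, the end-of-year established-colony census equilibrates
  at ≈ 87–89% of the capacity normalization constant N (stable across
  fixture scales; the end-of-year age ≥ 1 census sits at ≈ 133%). The
  published model reports holding N with the same 0.95 offspring
  calibration, which implies its spatial pattern statistics (reported as
  over-dispersed) differed from the near-Poisson patterns this engine
  produces. We keep the printed constants rather than re-deriving the
  calibration, and report the census deviation openly.
* **Suppression tempo.** The spatial drive sweep matches the structural
  mating-table recursion generation by generation, but reaching 90%
  biomass reduction under a perfect drive takes ≈ 59 years here versus
  the published ≈ 30; the slow phase is the asymptotic approach of the
  recruitment deficit to one (drive × drive matings yield only culled
  sterile daughters) under density-dependent compensation. The published
  tempo is not derivable from the printed model description.
* The generator emulates demographic stochasticity, spatial competition
  and mating locality; it does not model habitat heterogeneity, landscape
  barriers, within-year dynamics, worker-level behaviour, sperm depletion
  or functional (target-preserving) resistance alleles. Passing tests
  therefore demonstrate internal consistency with the stated model, not
  field realism.
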