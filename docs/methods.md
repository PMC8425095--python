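# Methods

## Model

`hivesim` simulates a small, closed honeybee (*Apis mellifera*) breeding
program under the infinitesimal model with maternal effects.  A colony's
performance is

    P = BV_mat^Q + mean(BV_dir^W) + e,        e ~ N(0, sigma_e^2),

the sum of the queen's maternal genetic effect, the mean direct genetic
effect of her worker group, and a non-heritable residual.  Every diploid
female carries a pair of breeding values (BV_dir, BV_mat); in the base
population these are bivariate normal with mean zero and covariance

    Sigma_BV = [[var_dir, cov], [cov, var_mat]],   cov = r * sqrt(var_dir * var_mat).

Raw colony performance is the sole selection criterion — no BLUP or other
pedigree-based evaluation is applied.

### Inheritance

Honeybees are haplodiploid.  Drones arise from unfertilized eggs and are
genetically gametes of their dam (a drone-producing queen, DPQ):

    BV^D = 1/2 BV^DPQ + phi^DPQ.

Queens inherit from their dam and from one sire drone picked uniformly at
random among the dam's nD mates; drones produce identical (mitotic)
gametes, so only the dam contributes a Mendelian sampling term:

    BV^Q = 1/2 BV^BQ + BV^D + phi^BQ.

Each Mendelian term phi is drawn from N(0, (1 - F)/4 * Sigma_BV) with F
the inbreeding coefficient of the meiotic parent, so inbreeding erodes
within-family variance — the only effect of inbreeding in the model (no
inbreeding depression on performance, no csd-locus/diploid-male
accounting).  The worker group is summarized by its mean breeding value,
half the queen's plus the mean of her mates'; the averaged Mendelian
terms of thousands of workers are taken as zero.  Drones from the
unselected environment (used during build-up) are drawn from
N(0, Sigma_BV / 2) — half the diploid variance, one gamete.

### Analytic expectations

For initial-population colonies, these rules give

    sigma_P^2 = var_mat + (nD + 2)/(4 nD) * var_dir + cov + sigma_e^2,

with the direct-effect weight 3/4 under monoandry (nD = 1) falling toward
1/4 for large nD; heritabilities are h2 = var / sigma_P^2.
`expectations.variance_in_year` applies the same formula to the genetic
(co)variances of any later cohort, which is only approximate once
breeding queens and DPQ become related.  These closed forms are never
used by the simulator itself (which records empirical moments only); they
serve as oracles in the test suite and to standardize outputs.

## Kinship

Coancestry is tracked with the tabular method for sex chromosomes /
haplodiploids: f(d, j) = f(dam, j) for a drone, f(i, j) = (f(dam, j) +
f(sire, j))/2 for a female, F = f(dam, sire), f(i, i) = (1 + F)/2 for
females and 1 for drones.  Two implementation choices matter:

* **Lazy drone rows.**  A drone with no descendants has exactly his dam's
  coancestry vector, so drones are stored as lightweight (dam, year)
  records and promoted to full matrix rows only when first used as a
  sire.  Since at most the 6 breeding queens' mates sire offspring in a
  given year, the matrix stays small even under high polyandry.  The
  promotion applies the exact tabular rule; results are identical to the
  naive method (verified against gene-dropping in the tests).
* **Pruning.**  Each simulated year, individuals more than 3 birth-years
  old are dropped *unless* they are a parent of a retained individual.
  Retained entries are copied verbatim, so every inbreeding coefficient
  computed after pruning is exactly what the unpruned table would give
  (this exactness is asserted in the tests).  "Generation" is interpreted
  as birth-year age, which matches the one-year dam-path generation
  interval.

A Monte Carlo gene-dropping routine (`gene_drop_kinship`) provides an
independent oracle: founders get unique alleles, transmission follows the
haplodiploid rules, and the per-replicate statistic is the exact IBD
probability given the replicate's allele configuration.

## Breeding plan

Defaults mirror a real French royal-jelly breeding association's scheme:

| parameter | default | meaning |
|---|---|---|
| breeding queens | 6 | dams of each year's cohort |
| virgin queens / BQ | 24 | candidate queens (144 total) |
| potential DPQ / BQ | 36 | sire candidates (216 total) |
| first-winter survival | 0.75 | 144 -> 108 candidates, 216 -> 162 pDPQ |
| second-winter survival | 2/3 | 162 -> 108 two-year pDPQ |
| DPQ families x per family | 4 x 3 | two-step sire selection |
| nD | 1 / 8 / 16 | drones per queen, one DPQ per queen |
| burn-in years | 3 | environment drones before closure |
| total years | 23 | 3 build-up + 20 closed selection |

Mortality is fixed-count (exact survivor numbers, random identities), as
the plan's post-winter counts are fixed.  The annual cycle for cohort t:
breed 360 daughters from the 6 breeding queens; mate every daughter
(environment drones for t <= 3, otherwise nD drones of a single DPQ born
in year t-2, with the 4 DPQ families assigned to equal numbers of queens
and the DPQ uniform within family); apply the first winter; phenotype the
108 surviving candidates and 162 surviving pDPQ in year t+1; select the 6
next breeding queens from the 108 (mass: best overall; within-line: best
per maternal line, an extinct line being replaced by splitting a random
surviving line); apply the second winter to last year's pDPQ and select
the DPQ cohort (4 best families by mean phenotyped performance among
those with at least one two-winter survivor, then up to 3 best
survivors per family, a 1-2 survivor family still supplying its full
drone share).  Potential DPQ are mated like virgin queens so their
colonies can be phenotyped; their mates never enter the gene pool (drones
inherit from the dam only).  Performance ties are broken uniformly at
random.

Year-1 initialization: 6 founder queens drawn from the base population
(F = 0, BV ~ N(0, Sigma_BV)), one maternal line each, mated to
environment drones; queen-side selection operates from the first
phenotyped cohort onward.  DPQ selected from pDPQ born in year 2 are the
first population sires, used in year 4; pDPQ born in year 1 are simulated
but never used as sires.

### Reported statistics

Per year and replicate the simulator records, over the 108 phenotyped
candidate queens born that year (a uniformly random, hence unbiased,
subset of the cohort; a switch can include the surviving pDPQ):
mean inbreeding F; mean and variance of BV_dir and BV_mat and their
correlation; mean and variance of the colony performances realized the
following year (so the year-23 entry holds year-24 performances).
Cross-replicate aggregation takes the mean and SD of each within-replicate
statistic.  Standardization divides performance by the analytic initial
sigma_P (above) and breeding values by sqrt(var_dir), sqrt(var_mat).
The inbreeding rate is the least-squares slope of mean F (in %) against
year over years 7-23.

## Randomness and reproducibility

Each replicate consumes a single `numpy` Generator seeded from a child of
`SeedSequence(master_seed)`, so scenarios are bit-reproducible given the
master seed and replicate count, and replicates are independent.  All
stochastic steps — base sampling, meiosis, mate assignment, winter culls,
tie-breaking — draw from that one stream.

## Scaled problem sizes

The study conditions (demography, parameters, 23 years) are simulated in
full; only the replicate count is scaled: 40 replicates in the test
suite and 48 in `scripts/acceptance.py`, versus 160 in the study.  At
these sizes the standard error of final mean inbreeding is ~0.4-0.8
percentage points and of standardized performance ~0.06-0.09, small
enough for three-standard-error comparisons against the published values.

## Degenerate inputs and numerical notes

Zero genetic variances, |r| = 1 and zero residual variance are all valid
(the 2x2 covariance factor is built explicitly, so singular setups do not
raise); inbreeding coefficients are clipped to [0, 1] to absorb
floating-point drift of order 1e-16 in the tabular recursions; the
coancestry buffer is grown geometrically and its unused region is never
read.  `winter_cull` requires survivor counts no larger than the group;
a closed year without an available DPQ cohort, fewer candidates than
breeding-queen slots, or fewer than 4 DPQ families with survivors abort
the replicate (counted, and the scenario fails if more than 5% of
replicates abort — with full-size cohorts these states are effectively
unreachable).

## What the simulator does and does not capture

It captures the sampling noise of a small real breeding population:
finite family sizes, random winter losses, line extinction/splitting, and
the interplay of selection, polyandry and haplodiploid inbreeding.  It
does not model inbreeding depression, csd homozygosity (diploid males),
finite-locus genetic architectures, mutation, open-population imports, or
queen lifespan differences between mating systems — so absolute
performance trajectories should be read as upper bounds for real
programs, while comparisons *between* strategies are the intended use.
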