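# Methods

## Ancestral haplotype tracking

The unit of analysis is the **core**: a window of `core_size` consecutive
SNPs (default 100) laid over the genome-wide *concatenated* SNP index.
Tiling ignores chromosome boundaries and drops the trailing remainder, so
the number of cores is exactly `floor(n_snps / 100)` — 528 cores for a
52,830-SNP panel, 7,352 for 735,239 SNPs, 7,147 for 714,759 SNPs. A
per-chromosome tiling (restarting at every chromosome, dropping each
chromosome's remainder) is available via
`partition_cores_by_chromosome` for users who prefer cores that never
straddle a boundary; it yields slightly fewer cores.

Within a core, haplotypes are discrete library entries: two strands carry
the same haplotype only when their allele sequences match exactly. No
mismatch tolerance is applied — the method treats phased haplotypes as
exact objects, and any phasing or genotyping error budget is the phasing
tool's concern, upstream of this package. Haplotype ids are assigned per
core in first-observed strand order, which makes catalogues reproducible;
all cross-population comparisons match by sequence, never by id.

**Ancestral set.** Per population, the base generation is the oldest
generation with phased animals (auto-detected, overridable — real
pedigrees sometimes lack genotypes for their earliest recorded
generations). Every haplotype observed there is ancestral; base
frequencies are counts over `2 x n_animals` strands.

**Statistics.** Per later generation (or pooling all post-base
generations for a "total population" figure):

- *proportion segregating*: per core `|ancestral ∩ observed| / |ancestral|`,
  averaged unweighted over cores. Equals 1 at the base generation by
  construction. The pooled variant excludes the base generation by default
  (its inclusion makes the statistic trivially 1); `include_base=True`
  restores the pooled-with-base reading.
- *molecular co-ancestry*: per core `f = Σ_i Σ_j p_i p_j s_ij` over the
  ancestral haplotypes still segregating, with `p` renormalised over those
  survivors and `s_ij` the proportion of identical alleles; self-pairs are
  included (`s_ii = 1`), so fixation of a single ancestral haplotype gives
  `f = 1`. This frequency-weighted form is the standard molecular
  co-ancestry; it is the default because it is the quantity whose rise
  toward 1 under drift and selection the method is designed to display. An
  unweighted mode (simple mean of off-diagonal `s_ij`; defined as 1 when a
  single haplotype survives) is selectable. Cores where no ancestral
  haplotype segregates in the target generation are excluded from that
  generation's mean — the statistic is undefined there — and reported as
  NaN per core.
- *haplotype variability*: distinct haplotypes per core pooling all
  generations of a population, averaged over cores.
- *sharing*: percentage of population A's ancestral haplotype sequences
  observed anywhere in population B (all generations pooled), computed on
  an identical partition of an identical SNP index.
- *mean ancestral frequency*: reported both cores-first (average per-core
  summed ancestral frequency) and haplotypes-first (average over
  individual ancestral haplotypes); cores-first is the default, consistent
  with how the other genome-wide averages are formed.

**Trends.** Ordinary least squares of the statistic on generation number
(`scipy.stats.linregress`), full range or restricted to the first `k`
generations after the base. `first_k = 3` spans generations base..base+3
inclusive — four points — which is the natural reading of "the decrease
over the first three generations" (three generation *intervals*); the
full-range fit is always reported alongside, so the distinction is visible
in output rather than hidden in a convention. Proportions are regressed on
the 0–1 scale; `TrendFit.slope_percent` rescales to percentage points per
generation.

## Forward simulator

The validation scenario is a discrete-generation forward simulation:

1. **Base population**: `n_base_males + n_base_females` diploids
   (defaults 200 + 200), every allele Bernoulli(0.5).
2. **Burn-in** (default 40,000 generations): random monogamous male–female
   pairing, every pair contributing exactly one son and one daughter.
   Equalising family sizes halves the variance of contributions and gives
   Ne ≈ 2N, which is the intended reading of "equal contributions" toward
   mutation–drift balance; the census and sex ratio are constant
   throughout. Mutation is a reversible two-allele flip (0 ↔ 1) at
   1e-4 per site per gamete — the only biallelic model whose equilibrium
   frequency spectrum is symmetric around 0.5. Recombination: crossover
   counts per chromosome ~ Poisson(1) with breakpoints uniform on the
   1-Morgan genetic length, no interference; the starting strand of each
   chromosome is uniform.
3. **Traits**: SNPs with MAF > 0.05 at the end of burn-in are eligible;
   round(30 %) of them become QTL. Per-trait effect scale
   `α_t = sqrt(Va_t / (2 n p q))` at the design point p = q = 0.5 with
   `Va = h² Vp` (h² = 0.1, 0.25, 0.8; Vp = 1). Per-QTL effects for the
   three traits are one joint draw from a zero-mean multivariate normal
   with marginal SDs `α` and correlations (r12, r13, r23) =
   (0.5, −0.5, r23): a joint draw is the only construction that honours
   the stated cross-trait correlations when traits share QTL. r23 is not
   specified by the scenario; it defaults to 0 and is configurable (the
   correlation matrix is validated positive definite). True breeding value
   is `dosage @ effects` with raw 0/1/2 dosages (no centring — only
   variances and regressions are ever asserted, so centring is
   immaterial); phenotype adds an independent N(0, (1−h²)Vp) deviate per
   trait (environmental correlations 0).
4. **Breed split**: two breeds of 100 + 100 founders drawn from the base,
   sharing 50 % of founders split evenly by sex (50 shared males, 50
   shared females at the defaults). Founders are copied with fresh ids
   and unknown parents, so each breed's pedigree is self-contained from
   its own G0.
5. **Selection** (10 generations): within each sex, the top fraction by
   phenotype of the selected trait (30 % of males, 80 % of females;
   selected counts round half-up; phenotype ties break by id). Each
   offspring draws a sire and dam uniformly from the selected pools with
   replacement. Which trait is under selection is configurable (default
   trait 1); all animals of all generations retain pedigree, true phase,
   breeding values and phenotypes.

QTL remain ordinary panel SNPs by default; `exclude_qtl_from_panel`
removes them from the emitted phased panel for analyses that want a
neutral-marker panel.

Meiosis is vectorised: crossovers and chromosome starts are encoded as
parity increments on a strand-choice matrix and resolved with one
cumulative sum per gamete batch, and mutation positions are drawn as a
binomial count of flat indices (duplicates removed) rather than a dense
per-site Bernoulli mask. This keeps a 2,000-generation burn-in of 100
animals over 2,500 SNPs under ten seconds without any compiled extension.

## Quality control

Filter order is fixed and reported: non-autosomal loci out; loci kept
only when call rate is **strictly greater** than 0.95; samples removed
when call rate over surviving loci is **strictly lower** than 0.95; then,
when trios are available, loci with Mendelian error rate **strictly
greater** than 0.095 out. The strictness at the boundaries is deliberate
and documented because datasets with many loci sitting exactly at a
threshold will notice it. The Mendelian denominator counts fully-called
trios only, which avoids inflating rates from missingness. Half-called
genotypes are missing. No minor-allele-frequency filter exists anywhere
in the package: rare haplotypes carry exactly the diversity signal the
method tracks.

## Pedigree metrics

MMG (maximum), MCG (complete) and MEG (equivalent) generations are
computed by memoised recursions in topological order; MEG uses
`MEG(x) = Σ over known parents p of (1/2)(1 + MEG(p))`, which equals the
per-path sum `Σ (1/2)^n` over known ancestors and handles inbreeding
loops without enumeration. MCG ≤ MEG ≤ MMG holds for every individual.
Realized effective size uses individual increases in inbreeding:
`dF_i = 1 − (1 − F_i)^(1/(MEG_i − 1))` for MEG_i > 1 and
`Ne = 1/(2 mean dF)`, with F from the tabular additive-relationship
recursion. This estimator was chosen because it is the standard Ne
estimator parameterised by equivalent generations; a fully outbred
pedigree yields dF = 0 and Ne is reported infinite rather than raising.
The recursion is quadratic in pedigree size — adequate for herd-scale
pedigrees (thousands of animals), not for national evaluations.

## Problem sizes used by the test and acceptance runs

The automated suite validates simulator behaviour at a reduced size chosen
to keep a complete run on one CPU in about a minute: 100 base animals,
2,000 burn-in generations, 5 chromosomes × 500 SNPs, breeds of 50, ten
selection generations, five replicates. At this size the drift law
`E[H_t] = H_0 (1 − 1/(2Ne))^t` (mutation off, Ne = 2N), the symmetry of
the equilibrium frequency spectrum, and the qualitative selection-era
pattern — co-ancestry slope positive, persistence slope negative in every
replicate — are all checked against replicate spread.
`scripts/acceptance.py` reports the quantities computed at this same
reduced size, plus the deterministic core counts. Absolute magnitudes at
the reduced size differ from full-size runs by construction: equilibrium
diversity scales with N·μ, so a smaller base population carries fewer,
shorter-lived haplotypes per core, a faster early persistence decay and a
steeper co-ancestry rise. Direction and structure of the results are
size-independent; per-core counts are not. Full-size runs
(`SimConfig()` defaults; hours of compute) go through the same code path
via `haplotrace replicate`.

## What the simulator does and does not emulate

It emulates: drift at equalised family sizes, mutation–recombination
balance, correlated polygenic traits, founder overlap between breeds, and
truncation selection with unequal sex-specific intensity — the forces the
tracking method is meant to resolve. It does not emulate: genotyping or
phasing error (the panel is true phase), dominance or epistasis, sex
chromosomes, crossover interference, overlapping generations, assortative
or avoidance mating, or unequal SNP spacing. Passing tests therefore
demonstrate correctness of the statistics and the expected
population-genetic response, not robustness to phasing artefacts in real
chip data — on real data the package deliberately consumes haplotypes
already phased by an external tool and treats them as exact.

## Known limitations

- Per-core similarity matrices are dense `k × k`; cores with many
  thousands of distinct haplotypes would be slow (not reached at
  realistic sizes).
- The co-ancestry of a generation in which *no* core retains an ancestral
  haplotype is undefined and raises; callers looping over deep
  trajectories should expect this at extreme drift.
- `GenotypePanel` holds the full matrix in memory (int8); HD-chip
  datasets of a few thousand animals fit comfortably, biobank scale does
  not.
- The pedigree Ne estimator assumes the pedigree is deep enough that
  MEG > 1 for a useful share of genotyped animals; shallow two-generation
  pedigrees yield no estimate (reported as NaN in summaries).
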