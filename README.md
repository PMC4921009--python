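# haplotrace

Tracking **ancestral haplotypes** across generations within and between
livestock populations.

Directional selection and genetic drift reshape the haplotype composition of
closed breeding populations: haplotypes present in the founder animals are
progressively lost, while those that remain grow more frequent and more
alike. `haplotrace` quantifies this process from phased SNP genotypes, for
breeders and population geneticists who want to follow founder genomes
through a pedigree — in real SNP-chip data or in forward simulations.

## Method

The genome-wide SNP index is partitioned into non-overlapping **cores** of
100 SNPs (the tiling ignores chromosome boundaries and drops the trailing
remainder, so a panel of 52,830 SNPs gives exactly 528 cores). Within each
core, every distinct allele sequence is a haplotype. The haplotypes observed
in the **base generation** — G0 of a simulation, or the oldest genotyped
generation of a real pedigree — are declared *ancestral*, with base
frequencies `p_i`. In each later generation the package computes, per core
and averaged genome-wide:

- the **proportion of ancestral haplotypes still segregating**,
  `|ancestral ∩ observed| / |ancestral|`;
- the **molecular co-ancestry** of the surviving ancestral haplotypes,
  `f = Σ_i Σ_j p_i p_j s_ij`, where `p` are the generation-specific
  frequencies renormalised over surviving ancestral haplotypes and `s_ij`
  is the proportion of identical alleles between haplotypes `i` and `j`
  (`s_ii = 1`); this is an identity-by-state analogue of kinship;
- the **haplotype variability**, the number of distinct haplotypes per core
  pooling all generations;
- between populations, the **percentage of one population's ancestral
  haplotypes observed anywhere in the other** (matched by exact sequence).

Trends over generations are summarised by simple linear regression on
generation number (slope `b`), optionally restricted to the first
generations after the base.

The package also implements the forward **Wright–Fisher simulator** used to
validate the method: a base population evolved to mutation–drift balance
under random mating with equalised family sizes (reversible two-allele
mutation, Poisson(1) crossovers per 1-Morgan chromosome), three genetically
correlated traits built from QTL with allelic-substitution effect scale
`α = sqrt(Va / 2npq)`, a split into two breeds sharing 50 % of founders, and
ten generations of truncation phenotypic selection (top 30 % of males, 80 %
of females). Pedigree-depth metrics (maximum, complete and equivalent
generations; realized Ne from individual increases in inbreeding) and
SNP-chip quality control (call-rate, autosome and trio Mendelian-error
filters — deliberately no MAF filter) round out the toolkit.

## Worked example

A reduced-size validation scenario (100 base animals, 2,000 burn-in
generations, 5 chromosomes × 500 SNPs, two breeds of 50 animals, ten
generations of selection):

```python
from haplotrace import SimConfig, simulate_scenario
from haplotrace.pipeline import analyze_scenario

config = SimConfig(
    n_base_males=50, n_base_females=50, n_burnin_generations=2000,
    n_chromosomes=5, n_snps_total=2500,
    breed_size_males=25, breed_size_females=25,
    n_selection_generations=10, random_seed=42,
)
result = simulate_scenario(config)
analysis = analyze_scenario(result, core_size=100)

print(f"cores analysed: {analysis['n_cores']}")
for pop, br in analysis["breeds"].items():
    print(f"breed {pop}: {br.haplotype_variability:.2f} haplotypes/core, "
          f"co-ancestry slope {br.coancestry_slope:.2e}, "
          f"persistence slope {100 * br.segregating_slope:.2f} %/generation")
for (a, b), pct in analysis["sharing"].items():
    print(f"ancestral haplotypes of {a} seen in {b}: {pct:.2f} %")
```

prints

```
cores analysed: 25
breed A: 163.32 haplotypes/core, co-ancestry slope 3.01e-03, persistence slope -6.63 %/generation
breed B: 163.80 haplotypes/core, co-ancestry slope 2.60e-03, persistence slope -6.65 %/generation
ancestral haplotypes of A seen in B: 72.37 %
ancestral haplotypes of B seen in A: 71.55 %
```

Read: each 100-SNP core carried on average ~163 distinct haplotypes across
the eleven generations; ancestral haplotypes were lost at ~6.6 % per
generation while the co-ancestry among the survivors rose each generation
(positive slope); and ~72 % of either breed's ancestral haplotypes were
also observed in the other breed, reflecting the half-shared founders.

## Command line

```bash
haplotrace simulate  --config cfg.yaml --out sim/ [--seed N] [--scale X]
haplotrace track     --panel sim/panel.phased --pedigree sim/pedigree.csv \
                     --core-size 100 --out track/
haplotrace share     --panel-a a.phased --panel-b b.phased \
                     --pedigree-a a.csv --pedigree-b b.csv --out share.csv
haplotrace qc        --ped data.ped --map data.map [--trios trios.csv] --out qc/
haplotrace pedstats  --pedigree ped.csv --out stats.csv
haplotrace trend     --series per_generation.csv [--first-k 3]
haplotrace annotate  --report top.csv --regions genes.bed --threshold 300000
haplotrace replicate --config cfg.yaml --scale 0.05 --replicates 3 --seed 1 --out rep/
```

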