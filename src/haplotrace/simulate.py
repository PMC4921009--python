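"""Forward-in-time simulation of two breeds derived from a common base.

The scenario: a closed base population evolves for many non-overlapping
generations under random mating with equalised family sizes (one son and one
daughter per monogamous pair), reversible two-allele mutation and Poisson
recombination, until it reaches mutation-drift balance.  Three genetically
correlated traits are then built from QTL sampled among the segregating
SNPs, the base is split into two breeds that share a configurable fraction
of founders, and each breed is propagated independently under truncation
phenotypic selection, keeping full pedigree and true phase for every animal
of every generation.

All sizes, rates and trait parameters live in :class:`SimConfig`; the
defaults describe the validation scenario (400 base animals, 40,000 burn-in
generations, 30 chromosomes of 1 Morgan carrying 52,830 evenly spaced SNPs,
mutation rate 1e-4, one expected crossover per chromosome and meiosis,
heritabilities 0.1/0.25/0.8, genetic correlations r12=0.5, r13=-0.5, 30 % of
males and 80 % of females selected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .haplotypes import PhasedPanel

UNKNOWN_PARENT = 0

MALE, FEMALE = 1, 2  # PLINK sex codes


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters; defaults are the validation-study values."""

    n_base_males: int = 200
    n_base_females: int = 200
    n_burnin_generations: int = 40_000
    n_chromosomes: int = 30
    chromosome_length: float = 1.0  # Morgans
    n_snps_total: int = 52_830
    mutation_rate: float = 1e-4  # per site, per gamete, per generation
    recombination_mean: float = 1.0  # expected crossovers per chromosome
    qtl_fraction: float = 0.30
    maf_floor: float = 0.05
    heritabilities: tuple[float, float, float] = (0.1, 0.25, 0.8)
    phenotypic_variances: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # (r12, r13, r23); r23 defaults to 0 and is configurable
    genetic_correlations: tuple[float, float, float] = (0.5, -0.5, 0.0)
    male_selected_fraction: float = 0.30
    female_selected_fraction: float = 0.80
    breed_size_males: int = 100
    breed_size_females: int = 100
    shared_founder_fraction: float = 0.5
    n_selection_generations: int = 10
    selection_trait_index: int = 0
    exclude_qtl_from_panel: bool = False
    random_seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_base_males",
            "n_base_females",
            "n_chromosomes",
            "n_snps_total",
            "breed_size_males",
            "breed_size_females",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_burnin_generations < 0 or self.n_selection_generations < 0:
            raise ValueError("generation counts must be non-negative")
        for name in ("mutation_rate", "qtl_fraction", "maf_floor",
                     "shared_founder_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("male_selected_fraction", "female_selected_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_snps_total % self.n_chromosomes != 0:
            raise ValueError(
                f"n_snps_total ({self.n_snps_total}) must divide evenly over "
                f"{self.n_chromosomes} chromosomes"
            )
        if any(not 0 < h <= 1 for h in self.heritabilities):
            raise ValueError("heritabilities must be in (0, 1]")
        if len(self.heritabilities) != 3 or len(self.phenotypic_variances) != 3:
            raise ValueError("exactly three traits are modelled")
        if not 0 <= self.selection_trait_index < 3:
            raise ValueError("selection_trait_index must be 0, 1 or 2")
        np.linalg.cholesky(self.correlation_matrix())  # positive definite

    @property
    def snps_per_chromosome(self) -> int:
        return self.n_snps_total // self.n_chromosomes

    def correlation_matrix(self) -> np.ndarray:
        r12, r13, r23 = self.genetic_correlations
        return np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])

    def scaled(self, factor: float) -> "SimConfig":
        """Shrink population sizes, burn-in length and SNP count by
        ``factor``, keeping all rates and the selection horizon fixed.

        Scaled runs are for smoke and property testing only: equilibrium
        diversity depends on N·mu, so shrinking N at fixed mu does not
        preserve the full-size expectations.
        """
        if not 0 < factor <= 1:
            raise ValueError("scale factor must be in (0, 1]")
        per_chrom = max(2, _round_half_up(self.snps_per_chromosome * factor))
        return replace(
            self,
            n_base_males=max(2, _round_half_up(self.n_base_males * factor)),
            n_base_females=max(2, _round_half_up(self.n_base_females * factor)),
            n_burnin_generations=_round_half_up(self.n_burnin_generations * factor),
            n_snps_total=per_chrom * self.n_chromosomes,
            breed_size_males=max(2, _round_half_up(self.breed_size_males * factor)),
            breed_size_females=max(2, _round_half_up(self.breed_size_females * factor)),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("heritabilities", "phenotypic_variances", "genetic_correlations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class GeneticMap:
    """Evenly spaced SNPs over equal-length chromosomes.

    ``morgan`` holds within-chromosome genetic positions; ``bp`` physical
    positions under a 1 cM/Mb convention (used only for annotation).
    """

    chrom: np.ndarray  # 1-based chromosome index per SNP
    morgan: np.ndarray  # position within chromosome, Morgans
    bp: np.ndarray
    chromosome_length: float

    @classmethod
    def evenly_spaced(
        cls,
        n_chromosomes: int,
        snps_per_chromosome: int,
        chromosome_length: float = 1.0,
    ) -> "GeneticMap":
        # midpoints of equal bins, so no SNP sits exactly on a chromosome edge
        within = (np.arange(snps_per_chromosome) + 0.5) * (
            chromosome_length / snps_per_chromosome
        )
        chrom = np.repeat(np.arange(1, n_chromosomes + 1), snps_per_chromosome)
        morgan = np.tile(within, n_chromosomes)
        bp = np.rint(morgan / chromosome_length * 100_000_000).astype(np.int64)
        return cls(chrom=chrom, morgan=morgan, bp=bp,
                   chromosome_length=chromosome_length)

    @classmethod
    def from_config(cls, config: SimConfig) -> "GeneticMap":
        return cls.evenly_spaced(
            config.n_chromosomes, config.snps_per_chromosome,
            config.chromosome_length,
        )

    @property
    def n_snps(self) -> int:
        return self.chrom.size

    @property
    def n_chromosomes(self) -> int:
        return int(self.chrom[-1])

    @property
    def chrom_start_index(self) -> np.ndarray:
        sizes = np.bincount(self.chrom)[1:]
        return np.concatenate([[0], np.cumsum(sizes)[:-1]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "snp_index": np.arange(self.n_snps),
             "morgan": self.morgan, "bp": self.bp}
        )


# ---------------------------------------------------------------------------
# population container
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """A cohort (or stacked cohorts) of diploid individuals.

    ``haplotypes`` has shape ``(n, 2, n_snps)`` (uint8, alleles 0/1).
    ``sire``/``dam`` use 0 for unknown parents.
    """

    ids: np.ndarray
    sex: np.ndarray  # 1 male, 2 female
    generation: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    haplotypes: np.ndarray
    label: str = "base"
    breeding_values: np.ndarray | None = None
    phenotypes: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.ids.size

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    def rows(self, mask: np.ndarray) -> "Population":
        return Population(
            ids=self.ids[mask],
            sex=self.sex[mask],
            generation=self.generation[mask],
            sire=self.sire[mask],
            dam=self.dam[mask],
            haplotypes=self.haplotypes[mask],
            label=self.label,
            breeding_values=None if self.breeding_values is None
            else self.breeding_values[mask],
            phenotypes=None if self.phenotypes is None else self.phenotypes[mask],
        )


def concatenate_populations(pops: Sequence[Population], label: str | None = None) -> Population:
    return Population(
        ids=np.concatenate([p.ids for p in pops]),
        sex=np.concatenate([p.sex for p in pops]),
        generation=np.concatenate([p.generation for p in pops]),
        sire=np.concatenate([p.sire for p in pops]),
        dam=np.concatenate([p.dam for p in pops]),
        haplotypes=np.concatenate([p.haplotypes for p in pops]),
        label=label if label is not None else pops[0].label,
        breeding_values=None if any(p.breeding_values is None for p in pops)
        else np.concatenate([p.breeding_values for p in pops]),
        phenotypes=None if any(p.phenotypes is None for p in pops)
        else np.concatenate([p.phenotypes for p in pops]),
    )


class _IdCounter:
    """Monotone id source; 0 is reserved for unknown parents."""

    def __init__(self, start: int = 1) -> None:
        self.next_id = start

    def take(self, n: int) -> np.ndarray:
        ids = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.next_id += n
        return ids


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def make_gametes(
    haplotypes: np.ndarray,
    parent_rows: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
    mutation_rate: float,
    recombination_mean: float = 1.0,
) -> np.ndarray:
    """Sample one gamete per entry of ``parent_rows`` (vectorised meiosis).

    Per chromosome the crossover count is Poisson(``recombination_mean``)
    with breakpoints uniform on the genetic length and the starting strand
    chosen with probability 1/2 (no interference).  Mutation then flips each
    transmitted allele independently with probability ``mutation_rate``
    (reversible two-allele model).
    """
    parent_rows = np.atleast_1d(np.asarray(parent_rows, dtype=np.intp))
    n_gam = parent_rows.size
    n_snps = haplotypes.shape[2]
    n_chrom = gmap.n_chromosomes
    chrom_starts = gmap.chrom_start_index
    within = gmap.morgan[: n_snps // n_chrom]  # identical layout per chromosome

    # Parity encoding: +1 at every crossover column, a random 0/1 at every
    # chromosome start (carry-over parity XOR uniform is still uniform), then
    # a running cumulative sum mod 2 gives the strand per SNP.
    switch = np.zeros((n_gam, n_snps), dtype=np.int8)
    switch[:, chrom_starts] = rng.integers(0, 2, size=(n_gam, n_chrom), dtype=np.int8)
    k = rng.poisson(recombination_mean, size=(n_gam, n_chrom))
    total = int(k.sum())
    if total:
        gam_idx = np.repeat(np.arange(n_gam), k.sum(axis=1))
        chrom_idx = np.repeat(np.tile(np.arange(n_chrom), n_gam), k.ravel())
        pos = rng.random(total) * gmap.chromosome_length
        offset = np.searchsorted(within, pos, side="left")
        col = chrom_starts[chrom_idx] + offset
        keep = offset < within.size  # a crossover beyond the last SNP is silent
        np.add.at(switch, (gam_idx[keep], col[keep]), 1)
    strand = np.cumsum(switch, axis=1, dtype=np.int8) & 1  # wrap keeps parity

    paternal = haplotypes[parent_rows, 0, :]
    maternal = haplotypes[parent_rows, 1, :]
    gametes = np.where(strand == 0, paternal, maternal)

    if mutation_rate > 0:
        n_mut = rng.binomial(n_gam * n_snps, mutation_rate)
        if n_mut:
            flat = np.unique(rng.integers(0, n_gam * n_snps, size=n_mut))
            gametes.ravel()[flat] ^= 1
    return gametes


def make_gamete(
    parent: Population,
    row: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    mutation_rate: float,
    recombination_mean: float = 1.0,
) -> np.ndarray:
    """Single-meiosis convenience wrapper around :func:`make_gametes`."""
    return make_gametes(
        parent.haplotypes, np.array([row]), gmap, rng,
        mutation_rate, recombination_mean,
    )[0]


# ---------------------------------------------------------------------------
# base population and burn-in
# ---------------------------------------------------------------------------

def init_base_population(
    config: SimConfig,
    rng: np.random.Generator,
    ids: _IdCounter | None = None,
) -> Population:
    """Starting state of the burn-in: every allele Bernoulli(0.5)."""
    n = config.n_base_males + config.n_base_females
    ids = ids or _IdCounter()
    haps = rng.integers(0, 2, size=(n, 2, config.n_snps_total), dtype=np.uint8)
    sex = np.concatenate([
        np.full(config.n_base_males, MALE, dtype=np.int8),
        np.full(config.n_base_females, FEMALE, dtype=np.int8),
    ])
    return Population(
        ids=ids.take(n),
        sex=sex,
        generation=np.zeros(n, dtype=np.int64),
        sire=np.full(n, UNKNOWN_PARENT, dtype=np.int64),
        dam=np.full(n, UNKNOWN_PARENT, dtype=np.int64),
        haplotypes=haps,
        label="base",
    )


def run_burnin(
    population: Population,
    config: SimConfig,
    gmap: GeneticMap,
    rng: np.random.Generator,
    ids: _IdCounter | None = None,
    n_generations: int | None = None,
) -> Population:
    """Random mating with equalised contributions for ``n_generations``.

    Each generation: males and females are paired monogamously at random
    and every pair produces exactly one son and one daughter, which keeps
    the census constant and family sizes equal (Ne ~ 2N).  Pedigree is not
    retained through the burn-in; the returned cohort's parents are marked
    unknown, which makes it a founder generation for downstream analyses.
    """
    n_gen = config.n_burnin_generations if n_generations is None else n_generations
    if n_gen == 0:
        return population
    males = np.flatnonzero(population.sex == MALE)
    females = np.flatnonzero(population.sex == FEMALE)
    if males.size != females.size or males.size == 0:
        raise ValueError(
            f"burn-in needs equal non-zero sex counts, got {males.size} males "
            f"and {females.size} females"
        )
    n_pairs = males.size
    ids = ids or _IdCounter(int(population.ids.max()) + 1)
    haps = population.haplotypes
    gen0 = int(population.generation.max())
    for t in range(n_gen):
        mates = rng.permutation(n_pairs)
        sires = males  # pair j: (males[j], females[mates[j]])
        dams = females[mates]
        # one son + one daughter per pair; independent meioses throughout
        sire_rows = np.concatenate([sires, sires])
        dam_rows = np.concatenate([dams, dams])
        pat = make_gametes(haps, sire_rows, gmap, rng,
                           config.mutation_rate, config.recombination_mean)
        mat = make_gametes(haps, dam_rows, gmap, rng,
                           config.mutation_rate, config.recombination_mean)
        haps = np.stack([pat, mat], axis=1)
        males = np.arange(n_pairs)
        females = np.arange(n_pairs, 2 * n_pairs)
    n = 2 * n_pairs
    sex = np.concatenate([
        np.full(n_pairs, MALE, dtype=np.int8),
        np.full(n_pairs, FEMALE, dtype=np.int8),
    ])
    return Population(
        ids=ids.take(n),
        sex=sex,
        generation=np.full(n, gen0 + n_gen, dtype=np.int64),
        sire=np.full(n, UNKNOWN_PARENT, dtype=np.int64),
        dam=np.full(n, UNKNOWN_PARENT, dtype=np.int64),
        haplotypes=haps,
        label=population.label,
    )


def allele_frequencies(population: Population) -> np.ndarray:
    return population.haplotypes.mean(axis=(0, 1))


def expected_heterozygosity(population: Population) -> float:
    """Mean of 2p(1-p) over all sites."""
    p = allele_frequencies(population)
    return float(np.mean(2.0 * p * (1.0 - p)))


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

@dataclass
class TraitModel:
    """QTL positions and per-trait additive effects for the three traits."""

    qtl_indices: np.ndarray
    alpha: np.ndarray  # (3,) per-trait effect scale
    heritabilities: np.ndarray
    phenotypic_variances: np.ndarray
    additive_variances: np.ndarray
    correlation: np.ndarray
    effects: np.ndarray | None = None  # (n_qtl, 3)

    @property
    def n_qtl(self) -> int:
        return self.qtl_indices.size

    def to_frame(self) -> pd.DataFrame:
        if self.effects is None:
            raise ValueError("effects not drawn yet")
        return pd.DataFrame(
            {"snp_index": self.qtl_indices,
             "effect1": self.effects[:, 0],
             "effect2": self.effects[:, 1],
             "effect3": self.effects[:, 2]}
        )


def allelic_substitution_effect(va: float, n: int, p: float, q: float) -> float:
    """Effect scale alpha = sqrt(Va / (2 n p q)).

    Allocates a trait's additive genetic variance ``Va`` over ``n`` loci of
    allele frequencies ``p``/``q`` so that, at those frequencies, the summed
    per-locus variances ``2 p q alpha^2`` reproduce ``Va``.
    """
    if n <= 0:
        raise ValueError(f"QTL count must be positive, got {n}")
    if not 0.0 < p < 1.0 or not 0.0 < q < 1.0:
        raise ValueError(f"frequencies must be in (0, 1), got p={p}, q={q}")
    if va < 0:
        raise ValueError(f"variance must be non-negative, got {va}")
    return math.sqrt(va / (2.0 * n * p * q))


def assign_qtl(
    population: Population, config: SimConfig, rng: np.random.Generator
) -> TraitModel:
    """Sample QTL among segregating SNPs and fix the per-trait alpha.

    Eligible SNPs have MAF > ``maf_floor`` at the assignment generation;
    ``round(qtl_fraction x eligible)`` of them become QTL.  Alpha is
    computed with the design frequencies p = q = 0.5.
    """
    p = allele_frequencies(population)
    maf = np.minimum(p, 1.0 - p)
    eligible = np.flatnonzero(maf > config.maf_floor)
    if eligible.size == 0:
        raise ValueError("no SNP exceeds the MAF floor; cannot assign QTL")
    n_qtl = _round_half_up(config.qtl_fraction * eligible.size)
    if n_qtl == 0:
        raise ValueError("qtl_fraction too small: zero QTL would be assigned")
    chosen = np.sort(rng.choice(eligible, size=n_qtl, replace=False))
    h2 = np.asarray(config.heritabilities, dtype=float)
    vp = np.asarray(config.phenotypic_variances, dtype=float)
    va = h2 * vp
    alpha = np.array(
        [allelic_substitution_effect(v, n_qtl, 0.5, 0.5) for v in va]
    )
    return TraitModel(
        qtl_indices=chosen,
        alpha=alpha,
        heritabilities=h2,
        phenotypic_variances=vp,
        additive_variances=va,
        correlation=config.correlation_matrix(),
    )


def draw_qtl_effects(
    model: TraitModel, rng: np.random.Generator
) -> TraitModel:
    """Draw per-QTL effects from a joint zero-mean multivariate normal.

    Marginal standard deviations are the per-trait alpha and the
    cross-trait correlations come from the configured genetic correlation
    matrix, so the three traits share QTL with correlated effects.
    """
    try:
        chol = np.linalg.cholesky(model.correlation)
    except np.linalg.LinAlgError as exc:
        raise ValueError("genetic correlation matrix is not positive definite") from exc
    z = rng.standard_normal((model.n_qtl, 3))
    model.effects = (z @ chol.T) * model.alpha
    return model


def compute_phenotypes(
    population: Population,
    model: TraitModel,
    rng: np.random.Generator,
) -> Population:
    """Additive model: TBV = dosage @ effects; P = TBV + N(0, (1-h2) Vp).

    Dosages are raw 0/1/2 allele counts; environmental deviates are
    independent across traits (no environmental correlation).
    """
    if model.effects is None:
        raise ValueError("QTL effects have not been drawn")
    dosage = population.haplotypes[:, :, model.qtl_indices].sum(axis=1)
    bv = dosage.astype(np.float64) @ model.effects
    env_sd = np.sqrt((1.0 - model.heritabilities) * model.phenotypic_variances)
    env = rng.standard_normal(bv.shape) * env_sd
    population.breeding_values = bv
    population.phenotypes = bv + env
    return population


# ---------------------------------------------------------------------------
# breed formation and selection
# ---------------------------------------------------------------------------

def split_breeds(
    population: Population,
    config: SimConfig,
    rng: np.random.Generator,
    ids: _IdCounter,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[Population, Population]:
    """Found two breeds from the base cohort with partially shared founders.

    Each breed gets ``breed_size_males + breed_size_females`` founders; the
    shared fraction is split evenly by sex (e.g. 50 shared males + 50
    shared females at the defaults).  Founders are copied with fresh ids
    and unknown parents: each breed's pedigree starts at its own G0.
    """
    males = np.flatnonzero(population.sex == MALE)
    females = np.flatnonzero(population.sex == FEMALE)
    picks: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    for pool, n_breed in ((males, config.breed_size_males),
                          (females, config.breed_size_females)):
        n_shared = _round_half_up(config.shared_founder_fraction * n_breed)
        n_unique = n_breed - n_shared
        need = n_shared + 2 * n_unique
        if need > pool.size:
            raise ValueError(
                f"breed founder request needs {need} animals of one sex but "
                f"base population has only {pool.size}"
            )
        drawn = rng.choice(pool, size=need, replace=False)
        shared = drawn[:n_shared]
        uniq_a = drawn[n_shared : n_shared + n_unique]
        uniq_b = drawn[n_shared + n_unique :]
        picks[labels[0]].append(np.concatenate([shared, uniq_a]))
        picks[labels[1]].append(np.concatenate([shared, uniq_b]))

    breeds = []
    for lab in labels:
        rows = np.concatenate(picks[lab])
        founders = population.rows(rows)
        founders.label = lab
        founders.ids = ids.take(rows.size)
        founders.generation = np.zeros(rows.size, dtype=np.int64)
        founders.sire = np.full(rows.size, UNKNOWN_PARENT, dtype=np.int64)
        founders.dam = np.full(rows.size, UNKNOWN_PARENT, dtype=np.int64)
        breeds.append(founders)
    return breeds[0], breeds[1]


def select_parents(
    population: Population,
    male_fraction: float,
    female_fraction: float,
    trait_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Truncation selection on phenotype, within each sex.

    Returns row indices of selected sires and dams.  The count per sex is
    the fraction of that sex rounded half-up; ties on phenotype are broken
    by id order.
    """
    if population.phenotypes is None:
        raise ValueError("phenotypes must be computed before selection")
    for frac in (male_fraction, female_fraction):
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"selected fraction must be in (0, 1], got {frac}")
    out = []
    for sex_code, frac in ((MALE, male_fraction), (FEMALE, female_fraction)):
        rows = np.flatnonzero(population.sex == sex_code)
        if rows.size == 0:
            raise ValueError(f"no animals of sex code {sex_code} to select from")
        phen = population.phenotypes[rows, trait_index]
        order = np.lexsort((population.ids[rows], -phen))
        n_sel = max(1, _round_half_up(frac * rows.size))
        out.append(rows[order[:n_sel]])
    return out[0], out[1]


def simulate_selection_phase(
    breed_g0: Population,
    config: SimConfig,
    gmap: GeneticMap,
    model: TraitModel,
    rng: np.random.Generator,
    ids: _IdCounter,
) -> Population:
    """Propagate one breed for ``n_selection_generations`` under selection.

    Each generation, the top phenotypic fractions of each sex become the
    parent pool; every one of the ``breed_size_males + breed_size_females``
    offspring draws a sire and a dam from the pools with replacement.  The
    returned population stacks G0..Gn with full pedigree and true phase.
    """
    if breed_g0.phenotypes is None:
        compute_phenotypes(breed_g0, model, rng)
    cohorts = [breed_g0]
    current = breed_g0
    n_off = config.breed_size_males + config.breed_size_females
    for gen in range(1, config.n_selection_generations + 1):
        sires, dams = select_parents(
            current,
            config.male_selected_fraction,
            config.female_selected_fraction,
            config.selection_trait_index,
        )
        sire_rows = rng.choice(sires, size=n_off, replace=True)
        dam_rows = rng.choice(dams, size=n_off, replace=True)
        pat = make_gametes(current.haplotypes, sire_rows, gmap, rng,
                           config.mutation_rate, config.recombination_mean)
        mat = make_gametes(current.haplotypes, dam_rows, gmap, rng,
                           config.mutation_rate, config.recombination_mean)
        sex = np.concatenate([
            np.full(config.breed_size_males, MALE, dtype=np.int8),
            np.full(config.breed_size_females, FEMALE, dtype=np.int8),
        ])
        offspring = Population(
            ids=ids.take(n_off),
            sex=sex,
            generation=np.full(n_off, gen, dtype=np.int64),
            sire=current.ids[sire_rows],
            dam=current.ids[dam_rows],
            haplotypes=np.stack([pat, mat], axis=1),
            label=breed_g0.label,
        )
        compute_phenotypes(offspring, model, rng)
        cohorts.append(offspring)
        current = offspring
    return concatenate_populations(cohorts, label=breed_g0.label)


# ---------------------------------------------------------------------------
# scenario orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Everything downstream analysis needs from one simulated scenario."""

    config: SimConfig
    gmap: GeneticMap
    trait_model: TraitModel
    breeds: dict[str, Population]

    def panel(self) -> PhasedPanel:
        """True-phase panel over both breeds (optionally without QTL columns)."""
        combined = concatenate_populations(list(self.breeds.values()), label="all")
        labels = np.concatenate(
            [np.full(p.size, lab) for lab, p in self.breeds.items()]
        )
        keep = np.ones(self.gmap.n_snps, dtype=bool)
        snps = self.gmap.to_frame()
        if self.config.exclude_qtl_from_panel:
            keep[self.trait_model.qtl_indices] = False
            snps = snps.loc[keep].reset_index(drop=True)
        alleles = combined.haplotypes[:, :, keep].reshape(-1, int(keep.sum()))
        animals = pd.DataFrame(
            {"id": combined.ids, "population": labels,
             "generation": combined.generation, "sex": combined.sex}
        )
        return PhasedPanel(alleles=alleles, animals=animals, snps=snps)

    def pedigree(self) -> pd.DataFrame:
        frames = []
        for lab, pop in self.breeds.items():
            frames.append(pd.DataFrame(
                {"id": pop.ids, "sire": pop.sire, "dam": pop.dam,
                 "sex": pop.sex, "generation": pop.generation,
                 "population": lab}
            ))
        return pd.concat(frames, ignore_index=True)


def simulate_scenario(
    config: SimConfig, rng: np.random.Generator | None = None
) -> ScenarioResult:
    """Run the complete scenario: burn-in, traits, breed split, selection."""
    rng = rng or np.random.default_rng(config.random_seed)
    ids = _IdCounter()
    gmap = GeneticMap.from_config(config)
    base = init_base_population(config, rng, ids)
    base = run_burnin(base, config, gmap, rng, ids)
    model = assign_qtl(base, config, rng)
    draw_qtl_effects(model, rng)
    compute_phenotypes(base, model, rng)
    breed_a, breed_b = split_breeds(base, config, rng, ids)
    compute_phenotypes(breed_a, model, rng)
    compute_phenotypes(breed_b, model, rng)
    trajectories = {}
    for breed in (breed_a, breed_b):
        trajectories[breed.label] = simulate_selection_phase(
            breed, config, gmap, model, rng, ids
        )
    return ScenarioResult(
        config=config, gmap=gmap, trait_model=model, breeds=trajectories
    )
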