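"""Ancestral haplotype tracking within fixed-width SNP cores.

The central idea: partition the genome-wide SNP index into non-overlapping
cores (windows of ``core_size`` SNPs, 100 by default), enumerate the distinct
haplotype sequences observed in each core, declare the haplotypes present in
the base generation (the oldest genotyped generation of a population)
*ancestral*, and then follow those ancestral haplotypes through later
generations: their frequencies, the fraction of them still segregating, and
the frequency-weighted average pairwise allele identity between them (an
identity-by-state estimate of the molecular co-ancestry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POOLED = "pooled"
"""Scope sentinel: pool every post-base generation of the population."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorePartition:
    """Non-overlapping, contiguous windows over a concatenated SNP index.

    Windows are half-open 0-based ``[start, end)`` ranges, each exactly
    ``core_size`` SNPs wide; a trailing remainder shorter than ``core_size``
    is excluded.
    """

    windows: tuple[tuple[int, int], ...]
    core_size: int

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def n_snps_covered(self) -> int:
        return len(self.windows) * self.core_size


@dataclass
class PhasedPanel:
    """Phased haplotypes for a set of animals over an ordered SNP index.

    Parameters
    ----------
    alleles
        uint8 array of shape ``(2 * n_animals, n_snps)``; rows ``2i`` and
        ``2i + 1`` are the two strands of animal ``i``.  Alleles are 0/1.
    animals
        One row per animal with at least columns ``id``, ``population``,
        ``generation`` (integer), ``sex``.
    snps
        Optional per-SNP metadata (``chrom``, ``bp``, ...), one row per SNP.
    """

    alleles: np.ndarray
    animals: pd.DataFrame
    snps: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (strands x SNPs)")
        if self.alleles.shape[0] != 2 * len(self.animals):
            raise ValueError(
                f"{self.alleles.shape[0]} strand rows for "
                f"{len(self.animals)} animals (need exactly two per animal)"
            )
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def strand_info(self) -> pd.DataFrame:
        """Animal metadata repeated once per strand (two rows per animal)."""
        info = self.animals.loc[self.animals.index.repeat(2)].reset_index(drop=True)
        info["strand"] = np.tile([0, 1], self.n_animals)
        return info

    def subset_population(self, population: str) -> "PhasedPanel":
        mask = (self.animals["population"] == population).to_numpy()
        rows = np.repeat(mask, 2)
        return PhasedPanel(
            self.alleles[rows],
            self.animals.loc[mask].reset_index(drop=True),
            self.snps,
        )


@dataclass
class CoreCatalog:
    """Distinct haplotypes per core with per-(population, generation) counts.

    ``sequences[c]`` maps haplotype id (the list position) to the raw byte
    string of the core-sized allele vector; ids are assigned in
    first-observed strand order so rebuilding from the same panel is
    reproducible.  ``counts[(c, pop, gen)]`` is an integer array indexed by
    haplotype id.
    """

    partition: CorePartition
    sequences: list[list[bytes]]
    counts: dict[tuple[int, str, int], np.ndarray]
    populations: tuple[str, ...]
    generations: dict[str, tuple[int, ...]]

    def n_haplotypes(self, core: int) -> int:
        return len(self.sequences[core])

    def observed_ids(self, core: int, population: str, generation: int) -> np.ndarray:
        """Haplotype ids with non-zero count in one (population, generation)."""
        counts = self.counts.get((core, population, generation))
        if counts is None:
            return np.empty(0, dtype=np.intp)
        return np.flatnonzero(counts)

    def pooled_counts(
        self,
        core: int,
        population: str | None = None,
        generations: Iterable[int] | None = None,
    ) -> np.ndarray:
        """Counts summed over generations (and populations if unspecified)."""
        total = np.zeros(self.n_haplotypes(core), dtype=np.int64)
        for (c, pop, gen), counts in self.counts.items():
            if c != core:
                continue
            if population is not None and pop != population:
                continue
            if generations is not None and gen not in set(generations):
                continue
            total[: counts.size] += counts
        return total


@dataclass
class AncestralSet:
    """Per core, the haplotypes present in a population's base generation."""

    partition: CorePartition
    population: str
    base_generation: int
    ids: list[np.ndarray]
    frequencies: list[np.ndarray]
    sequences: list[list[bytes]]

    @property
    def n_total(self) -> int:
        return int(sum(len(i) for i in self.ids))


@dataclass
class CoancestryResult:
    """Genome-average molecular co-ancestry for one generation."""

    generation: int
    value: float
    per_core: np.ndarray  # NaN where no ancestral haplotype segregates
    n_cores_used: int
    mode: str


# ---------------------------------------------------------------------------
# partitioning and cataloguing
# ---------------------------------------------------------------------------

def partition_cores(n_snps: int, core_size: int = 100) -> CorePartition:
    """Lay ``floor(n_snps / core_size)`` non-overlapping cores over the
    concatenated genome-wide SNP index, dropping the trailing remainder.

    Chromosome boundaries are ignored: cores are placed over the single
    concatenated index, which is what makes the core count a pure function
    of the post-QC SNP count.  Use :func:`partition_cores_by_chromosome` to
    restart the tiling at every chromosome instead.
    """
    if core_size <= 0:
        raise ValueError(f"core_size must be positive, got {core_size}")
    if n_snps < 0:
        raise ValueError(f"n_snps must be non-negative, got {n_snps}")
    n_cores = n_snps // core_size
    windows = tuple((i * core_size, (i + 1) * core_size) for i in range(n_cores))
    return CorePartition(windows=windows, core_size=core_size)


def partition_cores_by_chromosome(
    chromosome_sizes: Sequence[int], core_size: int = 100
) -> CorePartition:
    """Per-chromosome variant: tiling restarts at each chromosome boundary,
    dropping each chromosome's remainder separately."""
    if core_size <= 0:
        raise ValueError(f"core_size must be positive, got {core_size}")
    windows: list[tuple[int, int]] = []
    offset = 0
    for size in chromosome_sizes:
        for i in range(size // core_size):
            windows.append((offset + i * core_size, offset + (i + 1) * core_size))
        offset += size
    return CorePartition(windows=tuple(windows), core_size=core_size)


def _first_observed_order(inverse: np.ndarray, n_uniq: int) -> np.ndarray:
    """Permutation mapping sorted-unique ids to first-observed ids."""
    first = np.full(n_uniq, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(first, inverse, np.arange(inverse.size))
    return np.argsort(first, kind="stable")


def catalog_core_haplotypes(
    panel: PhasedPanel, partition: CorePartition
) -> CoreCatalog:
    """Enumerate distinct haplotype sequences per core with stable ids.

    Ids are assigned in the order the sequence is first observed while
    scanning strands top to bottom.  Counts are tallied per
    (population, generation); per core they sum to twice the number of
    phased animals in that group.
    """
    if partition.windows and partition.windows[-1][1] > panel.n_snps:
        raise ValueError(
            f"partition extends to SNP {partition.windows[-1][1]} but panel "
            f"has only {panel.n_snps} SNPs"
        )
    strands = panel.strand_info()
    pops = strands["population"].to_numpy()
    gens = strands["generation"].to_numpy()
    group_keys = pd.MultiIndex.from_arrays([pops, gens])
    group_codes, group_index = pd.factorize(group_keys, sort=True)
    n_groups = len(group_index)

    sequences: list[list[bytes]] = []
    counts: dict[tuple[int, str, int], np.ndarray] = {}
    for core, (start, end) in enumerate(partition.windows):
        block = np.ascontiguousarray(panel.alleles[:, start:end])
        voids = block.view(np.dtype((np.void, block.shape[1]))).ravel()
        uniq, inverse = np.unique(voids, return_inverse=True)
        order = _first_observed_order(inverse, len(uniq))
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        hap_ids = rank[inverse]
        sequences.append([uniq[i].tobytes() for i in order])
        combined = group_codes * len(uniq) + hap_ids
        tallies = np.bincount(combined, minlength=n_groups * len(uniq))
        tallies = tallies.reshape(n_groups, len(uniq))
        for g, (pop, gen) in enumerate(group_index):
            counts[(core, pop, int(gen))] = tallies[g].astype(np.int64)

    populations = tuple(sorted(set(pops)))
    generations = {
        pop: tuple(sorted(int(g) for g in set(gens[pops == pop])))
        for pop in populations
    }
    return CoreCatalog(
        partition=partition,
        sequences=sequences,
        counts=counts,
        populations=populations,
        generations=generations,
    )


# ---------------------------------------------------------------------------
# ancestral haplotypes
# ---------------------------------------------------------------------------

def identify_ancestral_set(
    catalog: CoreCatalog,
    population: str,
    base_generation: int | None = None,
) -> AncestralSet:
    """Declare ancestral the haplotypes observed in the base generation.

    The base generation defaults to the oldest generation with phased
    animals in the population.  Base frequencies per core are the counts in
    the base generation normalised to sum to 1.
    """
    if population not in catalog.populations:
        raise ValueError(f"population {population!r} not in catalog")
    if base_generation is None:
        base_generation = catalog.generations[population][0]
    if base_generation not in catalog.generations[population]:
        raise ValueError(
            f"no phased animals for population {population!r} in "
            f"generation {base_generation}"
        )
    ids: list[np.ndarray] = []
    freqs: list[np.ndarray] = []
    seqs: list[list[bytes]] = []
    for core in range(len(catalog.partition)):
        counts = catalog.counts[(core, population, base_generation)]
        present = np.flatnonzero(counts)
        total = counts[present].sum()
        if total == 0:
            raise ValueError(
                f"base generation {base_generation} has no strands in core {core}"
            )
        ids.append(present)
        freqs.append(counts[present] / total)
        seqs.append([catalog.sequences[core][i] for i in present])
    return AncestralSet(
        partition=catalog.partition,
        population=population,
        base_generation=base_generation,
        ids=ids,
        frequencies=freqs,
        sequences=seqs,
    )


def proportion_segregating(
    ancestral: AncestralSet,
    catalog: CoreCatalog,
    generation: int | str = POOLED,
    include_base: bool = False,
) -> float:
    """Mean over cores of the fraction of ancestral haplotypes still observed.

    ``generation`` is either a single generation label or :data:`POOLED`,
    which pools every generation after the base (Tables-style "total
    population"); set ``include_base=True`` to pool the base generation as
    well.  At the base generation the value is exactly 1 by definition.
    """
    pop = ancestral.population
    if generation == POOLED:
        scope = [
            g
            for g in catalog.generations[pop]
            if include_base or g > ancestral.base_generation
        ]
        if not scope:
            raise ValueError("no post-base generations to pool")
    else:
        if generation not in catalog.generations[pop]:
            raise ValueError(f"generation {generation} absent for {pop!r}")
        scope = [int(generation)]

    fractions = []
    for core in range(len(catalog.partition)):
        anc = ancestral.ids[core]
        if anc.size == 0:
            logger.warning("core %d has an empty ancestral set; excluded", core)
            continue
        observed: set[int] = set()
        for g in scope:
            observed.update(catalog.observed_ids(core, pop, g).tolist())
        fractions.append(len(observed.intersection(anc.tolist())) / anc.size)
    if not fractions:
        raise ValueError("no core has a non-empty ancestral set")
    return float(np.mean(fractions))


def haplotype_variability(
    catalog: CoreCatalog, population: str | None = None
) -> float:
    """Average number of distinct haplotypes per core, pooling all
    generations (of one population if given, else of the whole catalog)."""
    if not catalog.sequences:
        raise ValueError("empty catalog")
    per_core = []
    for core in range(len(catalog.partition)):
        pooled = catalog.pooled_counts(core, population=population)
        per_core.append(int(np.count_nonzero(pooled)))
    return float(np.mean(per_core))


def mean_ancestral_frequency(
    ancestral: AncestralSet,
    catalog: CoreCatalog,
    generation: int,
    average: str = "cores",
) -> float:
    """Average generation-specific frequency of ancestral haplotypes.

    ``average="cores"`` (default) averages the per-core summed ancestral
    frequency over cores; ``average="haplotypes"`` averages the individual
    haplotype frequencies over all ancestral haplotypes genome-wide.
    """
    pop = ancestral.population
    per_core, per_hap = [], []
    for core in range(len(catalog.partition)):
        counts = catalog.counts.get((core, pop, generation))
        if counts is None:
            raise ValueError(f"generation {generation} absent for {pop!r}")
        total = counts.sum()
        f = counts[ancestral.ids[core]] / total if total else np.zeros(0)
        per_core.append(float(f.sum()))
        per_hap.extend(f.tolist())
    if average == "cores":
        return float(np.mean(per_core))
    if average == "haplotypes":
        return float(np.mean(per_hap))
    raise ValueError(f"unknown average mode {average!r}")


# ---------------------------------------------------------------------------
# similarity and co-ancestry
# ---------------------------------------------------------------------------

def pairwise_similarity(h1, h2) -> float:
    """Fraction of positions where two equal-length allele sequences agree."""
    a = np.frombuffer(h1, dtype=np.uint8) if isinstance(h1, bytes) else np.asarray(h1)
    b = np.frombuffer(h2, dtype=np.uint8) if isinstance(h2, bytes) else np.asarray(h2)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return float(np.mean(a == b))


def similarity_matrix(sequences: Sequence[bytes]) -> np.ndarray:
    """Symmetric unit-diagonal matrix of pairwise allele identities."""
    arr = np.stack([np.frombuffer(s, dtype=np.uint8) for s in sequences])
    return (arr[:, None, :] == arr[None, :, :]).mean(axis=2)


def molecular_coancestry(
    ancestral: AncestralSet,
    catalog: CoreCatalog,
    generation: int,
    mode: str = "weighted",
) -> CoancestryResult:
    """Genome-average similarity between segregating ancestral haplotypes.

    Per core, with ``p`` the generation-specific frequencies of the
    ancestral haplotypes still segregating (renormalised over those) and
    ``s`` their pairwise allele identity:

    * ``mode="weighted"`` (default): ``f = sum_i sum_j p_i p_j s_ij`` with
      self-pairs included (``s_ii = 1``) — the molecular co-ancestry.
    * ``mode="unweighted"``: the simple average of the off-diagonal
      ``s_ij`` (1.0 when a single haplotype remains).

    Cores where no ancestral haplotype segregates in the generation are
    excluded from the genome mean (the statistic is undefined there) and
    reported as NaN in ``per_core``.
    """
    if mode not in ("weighted", "unweighted"):
        raise ValueError(f"unknown mode {mode!r}")
    pop = ancestral.population
    if generation not in catalog.generations[pop]:
        raise ValueError(f"generation {generation} absent for {pop!r}")
    n_cores = len(catalog.partition)
    per_core = np.full(n_cores, np.nan)
    for core in range(n_cores):
        counts = catalog.counts[(core, pop, generation)]
        anc = ancestral.ids[core]
        seg = anc[counts[anc] > 0]
        if seg.size == 0:
            continue
        if seg.size == 1:
            per_core[core] = 1.0
            continue
        seqs = [catalog.sequences[core][i] for i in seg]
        s = similarity_matrix(seqs)
        if mode == "weighted":
            p = counts[seg] / counts[seg].sum()
            per_core[core] = float(p @ s @ p)
        else:
            off = s[~np.eye(seg.size, dtype=bool)]
            per_core[core] = float(off.mean())
    used = int(np.count_nonzero(~np.isnan(per_core)))
    if used == 0:
        raise ValueError("no core has a segregating ancestral haplotype")
    value = float(np.nanmean(per_core))
    return CoancestryResult(
        generation=int(generation),
        value=value,
        per_core=per_core,
        n_cores_used=used,
        mode=mode,
    )


def coancestry_series(
    ancestral: AncestralSet,
    catalog: CoreCatalog,
    mode: str = "weighted",
) -> pd.DataFrame:
    """Co-ancestry per generation of the ancestral set's population."""
    rows = [
        (g, molecular_coancestry(ancestral, catalog, g, mode=mode).value)
        for g in catalog.generations[ancestral.population]
    ]
    return pd.DataFrame(rows, columns=["generation", "coancestry"])


def segregating_series(
    ancestral: AncestralSet, catalog: CoreCatalog
) -> pd.DataFrame:
    """Proportion of ancestral haplotypes segregating, per generation."""
    rows = [
        (g, proportion_segregating(ancestral, catalog, g))
        for g in catalog.generations[ancestral.population]
    ]
    return pd.DataFrame(rows, columns=["generation", "proportion_segregating"])


# ---------------------------------------------------------------------------
# sharing between populations
# ---------------------------------------------------------------------------

def shared_ancestral_fraction(
    ancestral_a: AncestralSet,
    catalog_b: CoreCatalog,
    population: str | None = None,
) -> tuple[float, pd.DataFrame]:
    """Percentage of A's ancestral haplotypes observed anywhere in B.

    Haplotypes are matched by exact allele sequence (never by catalog id),
    so the result is invariant to id relabelling.  Both analyses must use
    the same partition over the same SNP index.  When ``catalog_b`` holds
    several populations, ``population`` restricts membership to one of
    them (all generations pooled either way).

    Returns the genome-wide percentage and a per-core breakdown.
    """
    if ancestral_a.partition != catalog_b.partition:
        raise ValueError("partitions differ between the two analyses")
    shared_total = 0
    anc_total = 0
    rows = []
    for core in range(len(ancestral_a.partition)):
        observed_b = {
            catalog_b.sequences[core][i]
            for i in np.flatnonzero(
                catalog_b.pooled_counts(core, population=population)
            )
        }
        n_anc = len(ancestral_a.sequences[core])
        n_shared = sum(1 for s in ancestral_a.sequences[core] if s in observed_b)
        shared_total += n_shared
        anc_total += n_anc
        rows.append((core, n_anc, n_shared))
    if anc_total == 0:
        raise ValueError("ancestral set is empty")
    breakdown = pd.DataFrame(rows, columns=["core", "n_ancestral", "n_shared"])
    return 100.0 * shared_total / anc_total, breakdown


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def top_frequent_ancestral(
    ancestral: AncestralSet,
    catalog: CoreCatalog,
    n_top: int = 5,
    snp_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """The ``n_top`` most frequent ancestral haplotypes genome-wide.

    Frequency pools all generations of the population.  Ties are broken by
    core index, then haplotype id.  If ``snp_table`` (per-SNP ``chrom`` and
    ``bp``) is supplied, each record carries physical coordinates of its
    core span.
    """
    if n_top <= 0:
        raise ValueError(f"n_top must be positive, got {n_top}")
    pop = ancestral.population
    records = []
    for core, (start, end) in enumerate(catalog.partition.windows):
        pooled = catalog.pooled_counts(core, population=pop)
        total = pooled.sum()
        for hap in ancestral.ids[core]:
            rec = {
                "core": core,
                "haplotype_id": int(hap),
                "frequency": pooled[hap] / total if total else 0.0,
                "snp_start": start,
                "snp_end": end,
            }
            if snp_table is not None:
                span = snp_table.iloc[start:end]
                chroms = span["chrom"].unique()
                rec["chrom"] = chroms[0] if len(chroms) == 1 else None
                rec["bp_start"] = int(span["bp"].iloc[0])
                rec["bp_end"] = int(span["bp"].iloc[-1])
            records.append(rec)
    frame = pd.DataFrame(records)
    frame = frame.sort_values(
        ["frequency", "core", "haplotype_id"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return frame.head(n_top)


def annotate_proximity(
    records: pd.DataFrame,
    regions: pd.DataFrame,
    threshold: int = 300_000,
) -> pd.DataFrame:
    """Distance from each haplotype span to the nearest annotated region.

    ``records`` needs ``chrom``, ``bp_start``, ``bp_end`` columns (as
    produced by :func:`top_frequent_ancestral` with a SNP table);
    ``regions`` is BED-like with ``chrom``, ``start``, ``end``, ``name``
    (0-based half-open).  A record is flagged when its distance to the
    nearest same-chromosome region is strictly below ``threshold``
    (overlap counts as distance 0).  With no region on the chromosome the
    distance is NaN and the flag False.
    """
    for col in ("chrom", "bp_start", "bp_end"):
        if col not in records.columns or records[col].isna().any():
            raise ValueError(f"records lack physical coordinates ({col})")
    out = records.copy()
    distances = np.full(len(out), np.nan)
    names = [None] * len(out)
    for i, rec in enumerate(out.itertuples(index=False)):
        same = regions[regions["chrom"].astype(str) == str(rec.chrom)]
        if same.empty:
            continue
        starts = same["start"].to_numpy()
        ends = same["end"].to_numpy()
        # gap between [bp_start, bp_end] and half-open [start, end)
        d = np.maximum(0, np.maximum(starts - rec.bp_end, rec.bp_start - ends + 1))
        overlap = (starts <= rec.bp_end) & (ends > rec.bp_start)
        d[overlap] = 0
        j = int(np.argmin(d))
        distances[i] = d[j]
        names[i] = same["name"].iloc[j] if "name" in same.columns else None
    out["nearest_region_distance"] = distances
    out["nearest_region"] = names
    out["within_threshold"] = (distances < threshold) & ~np.isnan(distances)
    return out
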