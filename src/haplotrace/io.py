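"""File formats and genotype quality control.

Readers and writers for the text formats the toolkit consumes and emits:
PLINK-style ``.ped``/``.map`` genotypes, phased haplotype tables (the
simulator's own dialect and the two-rows-per-animal layout produced by
long-range phasing tools), pedigree CSV, genetic-map tables and BED region
lists.  Quality control mirrors common practice for SNP-chip data: autosomal
loci only, locus call rate strictly above a threshold, sample call rate not
strictly below a threshold, an optional Mendelian-error filter from
genotyped trios, and deliberately **no** minor-allele-frequency filter
(rare alleles carry diversity information).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import PhasedPanel

MISSING = -1
_NON_AUTOSOMES = {"X", "Y", "XY", "MT", "M", "0"}


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Diploid genotype codes (0/1/2, -1 missing) over an ordered SNP index.

    ``genotypes[i, j]`` counts copies of the second-observed allele of SNP
    ``j`` in animal ``i``.  ``snps`` has one row per SNP: ``chrom``,
    ``snp_id``, ``cm``, ``bp``, ``a1``, ``a2``.
    """

    ids: list[str]
    genotypes: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.ids), len(self.snps)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.ids)} animals x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or -1 (missing)")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class QCReport:
    """Counts of what each filter removed, reconciling before/after."""

    snps_before: int = 0
    samples_before: int = 0
    snps_removed_non_autosome: int = 0
    snps_removed_call_rate: int = 0
    snps_removed_mendelian: int = 0
    samples_removed_call_rate: int = 0

    @property
    def snps_after(self) -> int:
        return (self.snps_before - self.snps_removed_non_autosome
                - self.snps_removed_call_rate - self.snps_removed_mendelian)

    @property
    def samples_after(self) -> int:
        return self.samples_before - self.samples_removed_call_rate

    def to_dict(self) -> dict:
        return {
            "snps_before": self.snps_before,
            "snps_removed_non_autosome": self.snps_removed_non_autosome,
            "snps_removed_call_rate": self.snps_removed_call_rate,
            "snps_removed_mendelian": self.snps_removed_mendelian,
            "snps_after": self.snps_after,
            "samples_before": self.samples_before,
            "samples_removed_call_rate": self.samples_removed_call_rate,
            "samples_after": self.samples_after,
        }


# ---------------------------------------------------------------------------
# PLINK text dialect
# ---------------------------------------------------------------------------

def read_map(path) -> pd.DataFrame:
    """PLINK ``.map``: chrom, snp id, genetic position (cM), bp."""
    frame = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str, "snp_id": str, "cm": float, "bp": np.int64},
    )
    if frame.isna().any().any():
        raise ValueError(f"malformed .map file: {path}")
    return frame


def read_genotypes(ped_path, map_path) -> GenotypePanel:
    """Read a PLINK ``.ped``/``.map`` pair into coded genotypes.

    Allele coding per SNP: ``a1`` is the first non-missing allele symbol
    encountered scanning animals in file order, ``a2`` the second; the
    genotype code counts ``a2`` copies.  '0' denotes a missing allele, and
    a half-called genotype is treated as fully missing.
    """
    snps = read_map(map_path)
    n_snps = len(snps)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    allele_codes: list[dict[str, int]] = [dict() for _ in range(n_snps)]

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_snps} "
                    f"fields, found {len(tokens)}"
                )
            ids.append(tokens[1])
            alleles = tokens[6:]
            coded = np.empty(n_snps, dtype=np.int8)
            for j in range(n_snps):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    coded[j] = MISSING
                    continue
                codes = allele_codes[j]
                for sym in (a, b):
                    if sym not in codes:
                        if len(codes) >= 2:
                            raise ValueError(
                                f"{ped_path} line {lineno}: SNP {j} has more "
                                f"than two alleles"
                            )
                        codes[sym] = len(codes)
                coded[j] = codes[a] + codes[b]
            rows.append(coded)

    snps = snps.copy()
    symbols_a1, symbols_a2 = [], []
    for codes in allele_codes:
        inv = {v: k for k, v in codes.items()}
        symbols_a1.append(inv.get(0, "0"))
        symbols_a2.append(inv.get(1, inv.get(0, "0")))
    snps["a1"] = symbols_a1
    snps["a2"] = symbols_a2
    genotypes = (np.vstack(rows) if rows
                 else np.empty((0, n_snps), dtype=np.int8))
    return GenotypePanel(ids=ids, genotypes=genotypes, snps=snps)


def write_genotypes(panel: GenotypePanel, ped_path, map_path) -> None:
    """Write the panel back to the PLINK text dialect."""
    panel.snps[["chrom", "snp_id", "cm", "bp"]].to_csv(
        map_path, sep="\t", header=False, index=False
    )
    a1 = panel.snps["a1"].to_numpy()
    a2 = panel.snps["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(panel.ids):
            fields = [str(animal), str(animal), "0", "0", "0", "-9"]
            for j, code in enumerate(panel.genotypes[i]):
                if code == MISSING:
                    fields.extend(("0", "0"))
                elif code == 0:
                    fields.extend((a1[j], a1[j]))
                elif code == 1:
                    fields.extend((a1[j], a2[j]))
                else:
                    fields.extend((a2[j], a2[j]))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _is_autosome(chrom: pd.Series) -> np.ndarray:
    labels = chrom.astype(str).str.upper()
    return (~labels.isin(_NON_AUTOSOMES) & labels.str.fullmatch(r"\d+")).to_numpy()


def qc_filter(
    panel: GenotypePanel,
    snp_call_rate: float = 0.95,
    sample_call_rate: float = 0.95,
    autosomes_only: bool = True,
    report: QCReport | None = None,
) -> tuple[GenotypePanel, QCReport]:
    """Marker then sample quality control; never filters on allele frequency.

    Order: non-autosomal loci out (if requested); loci kept only when their
    call rate is strictly greater than ``snp_call_rate``; samples removed
    when their call rate over the surviving loci is strictly lower than
    ``sample_call_rate``.  The strict inequalities are deliberate: a locus
    at exactly the threshold is removed, a sample at exactly the threshold
    is retained.
    """
    for thr in (snp_call_rate, sample_call_rate):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"call-rate threshold must be in [0, 1], got {thr}")
    report = report or QCReport()
    report.snps_before = panel.n_snps
    report.samples_before = panel.n_animals

    keep_snp = np.ones(panel.n_snps, dtype=bool)
    if autosomes_only:
        autosomal = _is_autosome(panel.snps["chrom"])
        report.snps_removed_non_autosome = int((~autosomal).sum())
        keep_snp &= autosomal

    called = panel.genotypes != MISSING
    with np.errstate(invalid="ignore"):
        snp_cr = called.mean(axis=0) if panel.n_animals else np.ones(panel.n_snps)
    passing = snp_cr > snp_call_rate
    report.snps_removed_call_rate = int((keep_snp & ~passing).sum())
    keep_snp &= passing

    sample_cr = (called[:, keep_snp].mean(axis=1)
                 if keep_snp.any() else np.ones(panel.n_animals))
    keep_sample = ~(sample_cr < sample_call_rate)
    report.samples_removed_call_rate = int((~keep_sample).sum())

    filtered = GenotypePanel(
        ids=[a for a, k in zip(panel.ids, keep_sample) if k],
        genotypes=panel.genotypes[np.ix_(keep_sample, keep_snp)],
        snps=panel.snps.loc[keep_snp].reset_index(drop=True),
    )
    return filtered, report


def mendelian_error_rates(
    panel: GenotypePanel, trios: list[tuple[str, str, str]]
) -> np.ndarray:
    """Per-SNP Mendelian error rate over fully-called trios.

    A trio is informative for a SNP only when offspring, sire and dam are
    all called there; the rate is impossible-transmission trios over
    informative trios (NaN where no trio is informative).
    """
    index = {a: i for i, a in enumerate(panel.ids)}
    try:
        rows = np.array([[index[o], index[s], index[d]] for o, s, d in trios])
    except KeyError as exc:
        raise ValueError(f"trio references unknown animal id {exc.args[0]!r}")
    if rows.size == 0:
        return np.full(panel.n_snps, np.nan)
    off = panel.genotypes[rows[:, 0]]
    sire = panel.genotypes[rows[:, 1]]
    dam = panel.genotypes[rows[:, 2]]
    informative = (off != MISSING) & (sire != MISSING) & (dam != MISSING)
    impossible = (
        ((off == 0) & ((sire == 2) | (dam == 2)))
        | ((off == 2) & ((sire == 0) | (dam == 0)))
        | ((off == 1) & (((sire == 0) & (dam == 0)) | ((sire == 2) & (dam == 2))))
    )
    n_inf = informative.sum(axis=0)
    n_err = (impossible & informative).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_inf > 0, n_err / np.maximum(n_inf, 1), np.nan)


def mendelian_error_filter(
    panel: GenotypePanel,
    trios: list[tuple[str, str, str]],
    threshold: float = 0.095,
    report: QCReport | None = None,
) -> tuple[GenotypePanel, QCReport]:
    """Drop SNPs whose trio Mendelian error rate strictly exceeds the
    threshold (default 0.095); SNPs with no informative trio are kept."""
    report = report or QCReport(
        snps_before=panel.n_snps, samples_before=panel.n_animals
    )
    rates = mendelian_error_rates(panel, trios)
    with np.errstate(invalid="ignore"):
        drop = rates > threshold
    drop = np.nan_to_num(drop).astype(bool)
    report.snps_removed_mendelian += int(drop.sum())
    filtered = GenotypePanel(
        ids=panel.ids,
        genotypes=panel.genotypes[:, ~drop],
        snps=panel.snps.loc[~drop].reset_index(drop=True),
    )
    return filtered, report


# ---------------------------------------------------------------------------
# phased panels
# ---------------------------------------------------------------------------

_PHASED_HEADER = "#haplotrace-phased id strand alleles..."


def write_phased(panel: PhasedPanel, path) -> None:
    """One header line, then two rows per animal: id, strand index, alleles."""
    with open(path, "w") as fh:
        fh.write(_PHASED_HEADER + "\n")
        for i, animal in enumerate(panel.animals["id"]):
            for strand in (0, 1):
                alleles = " ".join(map(str, panel.alleles[2 * i + strand]))
                fh.write(f"{animal} {strand} {alleles}\n")


def read_phased(
    path,
    dialect: str = "auto",
    pedigree: pd.DataFrame | None = None,
    population: str = "pop",
) -> PhasedPanel:
    """Read a phased panel in the simulator dialect or the bare
    two-rows-per-animal layout emitted by long-range phasing tools.

    ``dialect`` is ``"haplotrace"`` (header + id + strand column),
    ``"tworow"`` (id then alleles, strands implicit by row order) or
    ``"auto"`` (header line decides).  Population and generation labels are
    joined from ``pedigree`` (columns ``id``, ``generation``, optionally
    ``population`` and ``sex``) when given, else every animal gets
    generation 0 in one population.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if dialect == "auto":
        dialect = "haplotrace" if lines and lines[0].startswith("#") else "tworow"
    if dialect == "haplotrace":
        if not lines or not lines[0].startswith("#"):
            raise ValueError(f"{path}: missing header line")
        lines = lines[1:]
        skip = 2
    elif dialect == "tworow":
        skip = 1
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(lines) % 2:
        raise ValueError(f"{path}: odd number of strand rows")

    ids: list[str] = []
    strands: list[np.ndarray] = []
    width = None
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        animal, alleles = tokens[0], tokens[skip:]
        if width is None:
            width = len(alleles)
        elif len(alleles) != width:
            raise ValueError(
                f"{path} row {lineno}: {len(alleles)} alleles, expected {width}"
            )
        if lineno % 2 == 1:
            ids.append(animal)
        elif animal != ids[-1]:
            raise ValueError(
                f"{path} row {lineno}: strand rows of animal {ids[-1]!r} are "
                f"not adjacent (found {animal!r})"
            )
        strands.append(np.array(alleles, dtype=np.uint8))

    animals = pd.DataFrame({"id": ids})
    if pedigree is not None:
        ped = pedigree.copy()
        ped["id"] = ped["id"].astype(str)
        merged = animals.merge(ped, on="id", how="left", validate="one_to_one")
        if merged["generation"].isna().any():
            missing = merged.loc[merged["generation"].isna(), "id"].tolist()
            raise ValueError(f"animals missing from pedigree: {missing[:5]}")
        animals["generation"] = merged["generation"].astype(int)
        animals["population"] = (
            merged["population"] if "population" in merged else population
        )
        animals["sex"] = merged.get("sex", 0)
    else:
        animals["generation"] = 0
        animals["population"] = population
        animals["sex"] = 0
    return PhasedPanel(alleles=np.vstack(strands), animals=animals)


# ---------------------------------------------------------------------------
# pedigree, map and region tables
# ---------------------------------------------------------------------------

def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    """Pedigree CSV: id, sire, dam, sex, generation, population; 0 = unknown
    parent.  Generation labels, when absent, can be derived with
    :func:`derive_generations`."""
    ped = pd.read_csv(path)
    required = {"id", "sire", "dam"}
    if not required.issubset(ped.columns):
        raise ValueError(f"pedigree needs columns {sorted(required)}")
    return ped


def derive_generations(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Label generations as 1 + max(parent generations), founders at 0."""
    parents = {
        row.id: (row.sire, row.dam) for row in pedigree.itertuples(index=False)
    }
    memo: dict = {}

    def gen(animal) -> int:
        if animal in memo:
            return memo[animal]
        sire, dam = parents.get(animal, (0, 0))
        known = [p for p in (sire, dam) if p != 0 and p in parents]
        memo[animal] = 0 if not known else 1 + max(gen(p) for p in known)
        return memo[animal]

    out = pedigree.copy()
    out["generation"] = [gen(a) for a in out["id"]]
    return out


def write_map_table(gmap_frame: pd.DataFrame, path) -> None:
    gmap_frame.to_csv(path, index=False)


def read_map_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open): chrom, start, end, optional name."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if frame.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least chrom/start/end")
    frame = frame.iloc[:, :4] if frame.shape[1] >= 4 else frame.assign(name=None)
    frame.columns = ["chrom", "start", "end", "name"][: frame.shape[1]]
    if "name" not in frame.columns:
        frame["name"] = None
    frame["chrom"] = frame["chrom"].astype(str)
    return frame
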