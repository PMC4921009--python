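"""Independent brute-force reference implementations used only by tests.

Everything here works on plain Python tuples/dicts and explicit loops, with
no shared code paths with the package, so agreement is a genuine
cross-check rather than a tautology.
"""

from itertools import product


def strand_sequences(panel, start, end):
    """Core-sized allele tuples per strand, in panel row order."""
    return [tuple(int(a) for a in row[start:end]) for row in panel.alleles]


def strand_labels(panel):
    """(population, generation) per strand, two per animal."""
    labels = []
    for _, row in panel.animals.iterrows():
        labels.extend([(row["population"], int(row["generation"]))] * 2)
    return labels


def tally_core(panel, start, end):
    """Counts per distinct sequence per (population, generation)."""
    seqs = strand_sequences(panel, start, end)
    labels = strand_labels(panel)
    counts = {}
    for seq, label in zip(seqs, labels):
        counts.setdefault(label, {}).setdefault(seq, 0)
        counts[label][seq] += 1
    return counts


def distinct_in_core(panel, start, end, population=None):
    seqs = strand_sequences(panel, start, end)
    labels = strand_labels(panel)
    return len({
        s for s, (pop, _) in zip(seqs, labels)
        if population is None or pop == population
    })


def ancestral_sequences(panel, start, end, population, base_generation):
    seqs = strand_sequences(panel, start, end)
    labels = strand_labels(panel)
    return {
        s for s, lab in zip(seqs, labels) if lab == (population, base_generation)
    }


def proportion_segregating_core(panel, start, end, population, base_gen, scope_gens):
    anc = ancestral_sequences(panel, start, end, population, base_gen)
    seqs = strand_sequences(panel, start, end)
    labels = strand_labels(panel)
    observed = {
        s for s, (pop, g) in zip(seqs, labels)
        if pop == population and g in scope_gens
    }
    return len(anc & observed) / len(anc)


def similarity(a, b):
    return sum(x == y for x, y in zip(a, b)) / len(a)


def coancestry_core(panel, start, end, population, base_gen, generation):
    """Sum_i sum_j p_i p_j s_ij over segregating ancestral haplotypes."""
    anc = ancestral_sequences(panel, start, end, population, base_gen)
    seqs = strand_sequences(panel, start, end)
    labels = strand_labels(panel)
    counts = {}
    for s, lab in zip(seqs, labels):
        if lab == (population, generation) and s in anc:
            counts[s] = counts.get(s, 0) + 1
    if not counts:
        return None
    total = sum(counts.values())
    haps = sorted(counts)
    f = 0.0
    for hi, hj in product(haps, repeat=2):
        f += (counts[hi] / total) * (counts[hj] / total) * similarity(hi, hj)
    return f


def sharing_percentage(panel_a, panel_b, windows, population_a, base_gen_a):
    """Percent of A-ancestral sequences observed anywhere in panel B."""
    shared = total = 0
    for start, end in windows:
        anc = ancestral_sequences(panel_a, start, end, population_a, base_gen_a)
        observed_b = set(strand_sequences(panel_b, start, end))
        total += len(anc)
        shared += len(anc & observed_b)
    return 100.0 * shared / total


def enumerate_ancestral_paths(parents, animal):
    """All (ancestor, path-length) pairs, one entry per distinct path."""
    out = []
    sire, dam = parents.get(animal, (None, None))
    for p in (sire, dam):
        if p is not None:
            out.append((p, 1))
            out.extend((anc, depth + 1)
                       for anc, depth in enumerate_ancestral_paths(parents, p))
    return out


def meg_by_path_enumeration(parents, animal):
    return sum(0.5 ** depth for _, depth in
               enumerate_ancestral_paths(parents, animal))


def mmg_by_path_enumeration(parents, animal):
    paths = enumerate_ancestral_paths(parents, animal)
    return max((d for _, d in paths), default=0)


def ols_slope(xs, ys):
    """Closed-form least squares slope."""
    n = len(xs)
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    num = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
    den = sum((x - xbar) ** 2 for x in xs)
    return num / den
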