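"""Pedigree-depth statistics and pedigree-based effective population size.

Per-individual depth metrics over a (possibly incomplete) pedigree:

* maximum generations (MMG): the longest ancestral path to any founder;
* complete generations (MCG): the deepest fully-known ancestor layer;
* equivalent generations (MEG): sum of (1/2)^n over all known ancestors,
  counted once per distinct ancestral path of length n.

MEG admits the parental recursion ``MEG(x) = sum over known parents p of
(1/2) (1 + MEG(p))``, which is what is implemented (it equals per-path
summation and is robust to inbreeding loops).  The realized effective
population size follows the individual-increase-in-inbreeding estimator:
``dF_i = 1 - (1 - F_i)^(1/(MEG_i - 1))`` for animals with MEG_i > 1 and
``Ne = 1 / (2 mean(dF))``, with inbreeding coefficients F from the tabular
additive-relationship recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN = 0


class PedigreeTable:
    """Validated id -> (sire, dam) lookup with topological order.

    Accepts a DataFrame with columns ``id``, ``sire``, ``dam`` and
    optionally ``sex``, ``generation``, ``population``.  Unknown parents
    are the sentinel 0.  Parents referenced but not recorded as animals
    are treated as founders.  Cycles raise at construction.
    """

    def __init__(self, frame: pd.DataFrame, unknown=UNKNOWN) -> None:
        required = {"id", "sire", "dam"}
        if not required.issubset(frame.columns):
            raise ValueError(f"pedigree needs columns {sorted(required)}")
        if frame["id"].duplicated().any():
            dupes = frame.loc[frame["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate animal ids: {dupes[:5]}")
        self.frame = frame.reset_index(drop=True)
        self.unknown = unknown
        self.parents: dict = {}
        for row in self.frame.itertuples(index=False):
            sire = row.sire if row.sire != unknown else None
            dam = row.dam if row.dam != unknown else None
            self.parents[row.id] = (sire, dam)
        self._order = self._toposort()

    def _toposort(self) -> list:
        order, state = [], {}
        for start in self.parents:
            stack = [(start, iter(self._known_parents(start)))]
            if state.get(start):
                continue
            state[start] = 1  # visiting
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if state.get(p) == 1:
                        raise ValueError(f"pedigree cycle involving {p!r}")
                    if state.get(p) is None:
                        state[p] = 1
                        stack.append((p, iter(self._known_parents(p))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    order.append(node)
                    stack.pop()
        return order

    def _known_parents(self, animal) -> list:
        sire, dam = self.parents.get(animal, (None, None))
        return [p for p in (sire, dam) if p is not None]

    def __contains__(self, animal) -> bool:
        return animal in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    @property
    def ids(self) -> list:
        return list(self.parents)

    def topological_order(self) -> list:
        """Every referenced animal, parents before offspring."""
        return list(self._order)


def _require(ped: PedigreeTable, animal) -> None:
    if animal not in ped:
        raise KeyError(f"animal {animal!r} not in pedigree")


def max_generations_all(ped: PedigreeTable) -> dict:
    memo: dict = {}
    for animal in ped.topological_order():
        known = ped._known_parents(animal)
        memo[animal] = 0 if not known else 1 + max(memo[p] for p in known)
    return memo


def complete_generations_all(ped: PedigreeTable) -> dict:
    memo: dict = {}
    for animal in ped.topological_order():
        sire, dam = ped.parents.get(animal, (None, None))
        if sire is None or dam is None:
            memo[animal] = 0
        else:
            memo[animal] = 1 + min(memo[sire], memo[dam])
    return memo


def equivalent_generations_all(ped: PedigreeTable) -> dict:
    memo: dict = {}
    for animal in ped.topological_order():
        memo[animal] = sum(
            0.5 * (1.0 + memo[p]) for p in ped._known_parents(animal)
        )
    return memo


def max_generations(ped: PedigreeTable, animal) -> int:
    """Longest ancestral path from the animal to any founder (MMG)."""
    _require(ped, animal)
    return max_generations_all(ped)[animal]


def complete_generations(ped: PedigreeTable, animal) -> int:
    """Largest g with all 2^g ancestors at depth g known (MCG)."""
    _require(ped, animal)
    return complete_generations_all(ped)[animal]


def equivalent_generations(ped: PedigreeTable, animal) -> float:
    """Sum of (1/2)^n over known ancestors, once per distinct path (MEG)."""
    _require(ped, animal)
    return equivalent_generations_all(ped)[animal]


def inbreeding_coefficients(ped: PedigreeTable) -> dict:
    """F per animal via the tabular additive-relationship recursion.

    Builds the additive relationship matrix row by row in topological
    order; ``F_x = 0.5 * a(sire, dam)``.  Quadratic in pedigree size, which
    is fine for the herd-scale pedigrees this package targets.
    """
    order = ped.topological_order()
    index = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    F: dict = {}
    for i, animal in enumerate(order):
        sire, dam = ped.parents.get(animal, (None, None))
        si = index[sire] if sire is not None else None
        di = index[dam] if dam is not None else None
        f = 0.5 * A[si, di] if si is not None and di is not None else 0.0
        F[animal] = f
        row = np.zeros(n)
        if si is not None:
            row += 0.5 * A[si]
        if di is not None:
            row += 0.5 * A[di]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        A[i, i] = 1.0 + f
    return F


def effective_size(
    ped: PedigreeTable, genotyped_ids: list | None = None
) -> tuple[float, pd.DataFrame]:
    """Realized Ne from individual increases in inbreeding.

    Uses only animals with MEG > 1 (the increase is undefined otherwise).
    Returns ``inf`` for a fully outbred pedigree (all F = 0).  The second
    element details the per-animal F, MEG and dF used.
    """
    animals = list(genotyped_ids) if genotyped_ids is not None else ped.ids
    for a in animals:
        _require(ped, a)
    meg = equivalent_generations_all(ped)
    inbreeding = inbreeding_coefficients(ped)
    rows = []
    for a in animals:
        t = meg[a]
        if t <= 1.0:
            continue
        f = inbreeding[a]
        df = 1.0 - (1.0 - f) ** (1.0 / (t - 1.0))
        rows.append((a, f, t, df))
    if not rows:
        raise ValueError("no animal has MEG > 1; Ne is undefined")
    detail = pd.DataFrame(rows, columns=["id", "F", "MEG", "dF"])
    mean_df = float(detail["dF"].mean())
    ne = float("inf") if mean_df <= 0.0 else 1.0 / (2.0 * mean_df)
    return ne, detail


def summarize_pedigree(
    ped: PedigreeTable, genotyped_ids: list | None = None
) -> dict:
    """Pedigree-description summary: Ng, Np, MMG/MCG/MEG mean (range), Ne."""
    if len(ped) == 0:
        raise ValueError("empty pedigree")
    genotyped = list(genotyped_ids) if genotyped_ids is not None else ped.ids
    for a in genotyped:
        _require(ped, a)
    mmg = max_generations_all(ped)
    mcg = complete_generations_all(ped)
    meg = equivalent_generations_all(ped)
    summary: dict = {"Ng": len(genotyped), "Np": len(ped)}
    for name, table in (("MMG", mmg), ("MCG", mcg), ("MEG", meg)):
        values = np.array([table[a] for a in genotyped], dtype=float)
        summary[f"{name}_mean"] = float(values.mean())
        summary[f"{name}_min"] = float(values.min())
        summary[f"{name}_max"] = float(values.max())
    try:
        ne, _ = effective_size(ped, genotyped)
    except ValueError:
        ne = float("nan")
    summary["Ne"] = ne
    return summary
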