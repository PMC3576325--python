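"""Clustering-similarity metrics, the all-to-all "ladder", and the
module-pair Jaccard table.

Nine metrics are supported: Jaccard, Mirkin, Rand, Fowlkes–Mallows, mutual
information, variation of information, purity, inverse purity and the
F-measure.  Pair-counting metrics are computed from co-membership pair
counts under the rule that two items are co-clustered in a clustering iff
they share at least one module there (so overlapping clusterings are handled
naturally).  The information-theoretic metrics and purity use a
membership-slot contingency table; for overlapping inputs those are
approximations and flagged as such in output headers.

Partial coverage enters through the ``unclustered`` policy: by default every
item of the comparison universe that a clustering leaves unassigned is
treated as its own singleton module, which keeps the pair total C(n,2)
constant across the ensemble and makes ladder cells comparable; the
alternative policy ``exclude`` restricts the comparison to items clustered
in both clusterings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._format import fmt
from .ensemble import Clustering, Ensemble

__all__ = [
    "PairCounts",
    "Ladder",
    "ModulePairRow",
    "METRICS",
    "DISTANCE_METRICS",
    "pair_counts",
    "compare_clusterings",
    "ladder",
    "module_pair_table",
    "ladder_tsv",
    "module_pair_tsv",
]

METRICS = (
    "jaccard",
    "mirkin",
    "rand",
    "fowlkes_mallows",
    "mutual_information",
    "variation_of_information",
    "purity",
    "inverse_purity",
    "f_measure",
)

#: Metrics where larger means *less* similar (used by renderers to invert color ramps).
DISTANCE_METRICS = frozenset({"mirkin", "variation_of_information"})

_PAIR_METRICS = frozenset({"jaccard", "mirkin", "rand", "fowlkes_mallows"})


@dataclass(frozen=True)
class PairCounts:
    """Counts of unordered item pairs by co-membership in two clusterings.

    ``n11``: co-clustered in both; ``n10``: first only; ``n01``: second only;
    ``n00``: neither.  They sum to C(n, 2) over the comparison universe.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class Ladder:
    """Lower triangle of the all-to-all similarity matrix."""

    names: tuple
    metric: str
    values: np.ndarray  # k×k, cell (i,j) filled for i>j, rest NaN

    def cell(self, i: int, j: int) -> float:
        if i == j:
            raise ValueError("ladder has no diagonal")
        return float(self.values[max(i, j), min(i, j)])


@dataclass(frozen=True)
class ModulePairRow:
    """One overlapping module pair with its Jaccard score and set algebra."""

    left: str
    right: str
    jaccard: float
    intersection: frozenset
    left_diff: frozenset
    right_diff: frozenset

    @property
    def union(self) -> frozenset:
        return self.intersection | self.left_diff | self.right_diff


def _comembership(clustering: Clustering, index: dict) -> np.ndarray:
    """Boolean co-membership matrix over the indexed universe; diagonal False."""
    n = len(index)
    b = np.zeros((n, n), dtype=bool)
    for m in clustering.modules:
        idx = np.fromiter(
            (index[u] for u in m.members if u in index), dtype=np.intp
        )
        if idx.size:
            b[np.ix_(idx, idx)] = True
    np.fill_diagonal(b, False)
    return b


def _comparison_universe(c1, c2, universe, unclustered):
    if unclustered == "singleton":
        return list(universe)
    if unclustered == "exclude":
        both = c1.clustered_items & c2.clustered_items
        return [u for u in universe if u in both]
    raise ValueError(f"unknown unclustered policy {unclustered!r}")


def pair_counts(
    c1: Clustering,
    c2: Clustering,
    universe: Sequence,
    unclustered: str = "singleton",
) -> PairCounts:
    """Count unordered item pairs by co-membership in each clustering.

    A pair counts as co-clustered in a clustering iff both items share at
    least one module there; unclustered items behave as singletons under the
    default policy (they co-cluster with nothing).
    """
    items = _comparison_universe(c1, c2, universe, unclustered)
    index = {u: i for i, u in enumerate(items)}
    n = len(items)
    b1 = _comembership(c1, index)
    b2 = _comembership(c2, index)
    iu = np.triu_indices(n, k=1)
    a, b = b1[iu], b2[iu]
    n11 = int(np.count_nonzero(a & b))
    n10 = int(np.count_nonzero(a & ~b))
    n01 = int(np.count_nonzero(~a & b))
    n00 = int(a.size - n11 - n10 - n01)
    return PairCounts(n11=n11, n10=n10, n01=n01, n00=n00)


def _contingency(c1: Clustering, c2: Clustering, items: Sequence):
    """Membership-slot contingency table n_ij = |m_i ∩ m_j| with singleton
    pseudo-modules for items either clustering leaves unassigned."""
    itemset = set(items)

    def effective_modules(c):
        mods = [m.members & itemset for m in c.modules]
        mods = [m for m in mods if m]
        covered = set().union(*mods) if mods else set()
        mods.extend({u} for u in items if u not in covered)
        return mods

    mods1 = effective_modules(c1)
    mods2 = effective_modules(c2)
    table = np.array(
        [[len(a & b) for b in mods2] for a in mods1], dtype=float
    )
    return table


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _info_metrics(table: np.ndarray):
    total = table.sum()
    p = table / total
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    nz = p > 0
    mi = float((p[nz] * np.log2(p[nz] / np.outer(pi, pj)[nz])).sum())
    h1 = _entropy_bits(pi)
    h2 = _entropy_bits(pj)
    return mi, h1, h2


def compare_clusterings(
    c1: Clustering,
    c2: Clustering,
    metric: str,
    universe: Sequence,
    unclustered: str = "singleton",
) -> float:
    """Similarity (or distance, for Mirkin/VI) between two clusterings.

    Pair-counting metrics: Jaccard = n11/(n11+n10+n01);
    Rand = (n11+n00)/C(n,2); Fowlkes–Mallows = n11/√((n11+n10)(n11+n01));
    Mirkin = 2(n10+n01)/n² (normalized to [0,1]).  Information metrics over
    the joint slot contingency: MI (bits) and VI = H1+H2−2·MI.  Purity is
    the size-weighted best-overlap of c1's modules against c2's; inverse
    purity swaps the arguments; the F-measure is the size-weighted best
    harmonic mean of precision and recall over c2's modules.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")

    if metric in _PAIR_METRICS:
        pc = pair_counts(c1, c2, universe, unclustered)
        if metric == "jaccard":
            denom = pc.n11 + pc.n10 + pc.n01
            return pc.n11 / denom if denom else 1.0
        if metric == "rand":
            return (pc.n11 + pc.n00) / pc.total if pc.total else 1.0
        if metric == "fowlkes_mallows":
            m1 = pc.n11 + pc.n10
            m2 = pc.n11 + pc.n01
            if m1 == 0 and m2 == 0:
                return 1.0
            if m1 == 0 or m2 == 0:
                return 0.0
            return pc.n11 / math.sqrt(m1 * m2)
        # mirkin, normalized by n^2 to lie in [0,1]
        items = _comparison_universe(c1, c2, universe, unclustered)
        n = len(items)
        return 2.0 * (pc.n10 + pc.n01) / (n * n) if n else 0.0

    items = _comparison_universe(c1, c2, universe, unclustered)
    table = _contingency(c1, c2, items)
    total = table.sum()
    if metric in ("mutual_information", "variation_of_information"):
        mi, h1, h2 = _info_metrics(table)
        if metric == "mutual_information":
            return mi
        return max(h1 + h2 - 2.0 * mi, 0.0)
    if metric == "purity":
        return float(table.max(axis=1).sum() / total)
    if metric == "inverse_purity":
        return float(table.max(axis=0).sum() / total)
    # f_measure: van Rijsbergen form, weighted best-F over c2's modules
    ni = table.sum(axis=1)
    nj = table.sum(axis=0)
    f = 2.0 * table / (ni[:, None] + nj[None, :])
    return float((nj / total * f.max(axis=0)).sum())


def ladder(ensemble: Ensemble, metric: str, unclustered: str = "singleton") -> Ladder:
    """All-to-all similarity, lower triangle (cell (i,j) for i>j)."""
    k = ensemble.k
    if k < 2:
        raise ValueError("ladder needs at least two clusterings")
    values = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i):
            values[i, j] = compare_clusterings(
                ensemble.clusterings[i],
                ensemble.clusterings[j],
                metric,
                ensemble.universe,
                unclustered,
            )
    return Ladder(
        names=tuple(c.name for c in ensemble.clusterings),
        metric=metric,
        values=values,
    )


def module_pair_table(
    c1: Clustering,
    c2: Clustering,
    min_j: float = 0.0,
    max_j: float = 1.0,
) -> list:
    """All overlapping module pairs with Jaccard in [min_j, max_j].

    Rows are sorted by Jaccard descending, ties by (left, right) labels.
    """
    if not (0.0 <= min_j <= max_j <= 1.0):
        raise ValueError("need 0 <= min_j <= max_j <= 1")
    rows = []
    for m1 in c1.modules:
        for m2 in c2.modules:
            inter = m1.members & m2.members
            if not inter:
                continue
            j = len(inter) / len(m1.members | m2.members)
            if min_j <= j <= max_j:
                rows.append(
                    ModulePairRow(
                        left=m1.label,
                        right=m2.label,
                        jaccard=j,
                        intersection=frozenset(inter),
                        left_diff=frozenset(m1.members - m2.members),
                        right_diff=frozenset(m2.members - m1.members),
                    )
                )
    rows.sort(key=lambda r: (-r.jaccard, r.left, r.right))
    return rows


def ladder_tsv(lad: Ladder) -> str:
    """Ladder in long format: c1, c2, metric, value."""
    lines = ["c1\tc2\tmetric\tvalue"]
    k = len(lad.names)
    for i in range(k):
        for j in range(i):
            lines.append(
                f"{lad.names[i]}\t{lad.names[j]}\t{lad.metric}\t{fmt(lad.cell(i, j))}"
            )
    return "\n".join(lines) + "\n"


def module_pair_tsv(rows) -> str:
    lines = ["left\tright\tjaccard\tn_intersection\tintersection\tleft_diff\tright_diff"]
    for r in rows:
        lines.append(
            f"{r.left}\t{r.right}\t{fmt(r.jaccard)}\t{len(r.intersection)}\t"
            f"{','.join(sorted(r.intersection))}\t{','.join(sorted(r.left_diff))}\t"
            f"{','.join(sorted(r.right_diff))}"
        )
    return "\n".join(lines) + "\n"
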