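"""Dense-diagonal-block ("core") detection in a reordered co-cluster matrix.

A core is a contiguous diagonal block of the seriated A⁺ whose items
co-clustered more often than expected by chance.  The block [p, q]
(1-based, inclusive) has sum s(p,q) = Σ_{p≤i<j≤q} a⁺_ij and density

    d(p, q) = s(p, q) / h,   h = q − p + 1,

the weighted-subgraph density |E(S)|/|V(S)| when A⁺ is read as a weighted
adjacency matrix.  All block sums are computed in O(n²) via the column
recurrence s(p, q+1) = s(p, q) + Σ_{i=p..q} a_{i,q+1}.  A dynamic program

    D_opt(j) = max_{1≤i≤j} { D_opt(i−1) + d(i, j) }

partitions positions 1..n into contiguous blocks maximizing the summed
density (singleton blocks are allowed with d = 0).  Blocks are then kept
only if their density exceeds the null expectation under a uniform edge
model: with w_avg = s(1,n)/z̄ the average non-zero cell value and
P(e) = z̄/C(n,2) the edge probability,

    d_avg(p, q) = w_avg · P(e) · C(h,2) / h = s(1,n)·(h−1) / (n·(n−1)),

so the whole-matrix expectation equals the observed global density s(1,n)/n
and a uniform matrix yields no cores at all.

When the clusterings derive from a network, each core can be annotated with
its *cohesion* E_in/E_out — edges inside the core versus edges crossing its
boundary; low cohesion means the core is tightly wired into the rest of the
network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from ._format import fmt
from .cocluster import CoClusterMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BlockSums",
    "Core",
    "block_sums",
    "density",
    "find_cores",
    "expected_density",
    "filter_cores",
    "cohesion",
    "parse_network",
    "identify_cores",
    "cores_tsv",
]


@dataclass(frozen=True)
class BlockSums:
    """All strict-upper-triangle block sums s(p,q) of a symmetric matrix.

    Stored as an n×n array with ``s[p-1, q-1]`` = s(p, q) for p ≤ q
    (1-based bounds); the lower triangle is unused.
    """

    s: np.ndarray

    @property
    def n(self) -> int:
        return self.s.shape[0]

    def value(self, p: int, q: int) -> float:
        if not (1 <= p <= q <= self.n):
            raise ValueError(f"need 1 <= p <= q <= n, got ({p}, {q})")
        return float(self.s[p - 1, q - 1])

    @property
    def total(self) -> float:
        """s(1, n): sum of all strict-upper-triangle entries."""
        return float(self.s[0, -1])


@dataclass(frozen=True)
class Core:
    """A contiguous diagonal block [p, q] (1-based, inclusive) of the
    reordered matrix, with its density, null expectation and optional
    network cohesion."""

    p: int
    q: int
    members: tuple
    density: float
    expected_density: float
    cohesion: Optional[float] = None

    @property
    def size(self) -> int:
        return self.q - self.p + 1


def block_sums(values: np.ndarray) -> BlockSums:
    """All s(p, q) in O(n²) via s(p, q+1) = s(p, q) + Σ_{i=p..q} a_{i,q+1}."""
    a = np.asarray(values, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(a, a.T):
        raise ValueError("matrix must be symmetric")
    n = a.shape[0]
    s = np.zeros((n, n), dtype=np.float64)
    for j in range(1, n):  # 0-based column q+1
        col = a[:j, j]
        # t[p] = Σ_{i=p..j-1} a_{i,j}: reversed cumulative sum
        t = np.cumsum(col[::-1])[::-1]
        s[:j, j] = s[:j, j - 1] + t
    return BlockSums(s=s)


def density(sums: BlockSums, p: int, q: int) -> float:
    """Block density d(p,q) = s(p,q)/h with h = q−p+1 vertices; d(p,p) = 0."""
    return sums.value(p, q) / (q - p + 1)


def find_cores(aplus_reordered: CoClusterMatrix) -> list:
    """Optimal contiguous partition of 1..n by summed block density (unfiltered).

    Dynamic program over block ends; singleton blocks are permitted and
    carry zero density.  Ties prefer fewer blocks, then the first optimum
    encountered scanning block starts ascending.  Returns the full
    partition as :class:`Core` records annotated with density and expected
    density (cohesion unset).
    """
    values = aplus_reordered.values
    n = aplus_reordered.n
    sums = block_sums(values)
    zbar = aplus_reordered.zbar
    # D[j] = best score for positions 1..j; back[j] = start of final block
    score = np.zeros(n + 1)
    nblocks = np.zeros(n + 1, dtype=np.intp)
    back = np.zeros(n + 1, dtype=np.intp)
    srow = sums.s
    for j in range(1, n + 1):
        best_score = -math.inf
        best_nb = 0
        best_i = 1
        for i in range(1, j + 1):
            d = srow[i - 1, j - 1] / (j - i + 1)
            cand = score[i - 1] + d
            nb = nblocks[i - 1] + 1
            if cand > best_score or (cand == best_score and nb < best_nb):
                best_score, best_nb, best_i = cand, nb, i
        score[j] = best_score
        nblocks[j] = best_nb
        back[j] = best_i
    # backtrack
    bounds = []
    j = n
    while j > 0:
        i = int(back[j])
        bounds.append((i, j))
        j = i - 1
    bounds.reverse()
    cores = []
    for p, q in bounds:
        cores.append(
            Core(
                p=p,
                q=q,
                members=tuple(aplus_reordered.items[p - 1 : q]),
                density=density(sums, p, q),
                expected_density=(
                    expected_density(sums, zbar, n, p, q) if zbar > 0 else math.nan
                ),
            )
        )
    return cores


def expected_density(sums: BlockSums, zbar: int, n: int, p: int, q: int) -> float:
    """Null block density d_avg(p,q) = w_avg·P(e)·C(h,2)/h = s(1,n)·(h−1)/(n(n−1))."""
    if zbar <= 0:
        raise ValueError("expected density is undefined for an empty matrix (zbar = 0)")
    h = q - p + 1
    w_avg = sums.total / zbar
    p_edge = zbar / (n * (n - 1) / 2.0)
    return w_avg * p_edge * (h * (h - 1) / 2.0) / h


def filter_cores(cores: Sequence, sums: BlockSums, zbar: int, n: int) -> list:
    """Keep blocks denser than their null expectation (strict), annotated.

    With an empty matrix (zbar = 0) the null is undefined: no filtering is
    possible and no cores are reported.
    """
    if zbar <= 0:
        logger.warning("zbar = 0: expected density undefined, reporting no cores")
        return []
    kept = []
    for c in cores:
        exp = expected_density(sums, zbar, n, c.p, c.q)
        if c.density > exp:
            kept.append(replace(c, expected_density=exp))
    return kept


def cohesion(members: Sequence, network: nx.Graph) -> float:
    """E_in/E_out for a core against an undirected network.

    E_in counts edges with both endpoints inside the core, E_out edges with
    exactly one endpoint inside.  An isolated core (E_out = 0, E_in > 0)
    returns +inf; a core with no incident edges at all returns 0.
    """
    inside = set(members)
    e_in = e_out = 0
    for u in inside:
        if u not in network:
            continue
        for v in network[u]:
            if v in inside:
                e_in += 1
            else:
                e_out += 1
    e_in //= 2  # each internal edge visited from both endpoints
    if e_out == 0:
        return math.inf if e_in > 0 else 0.0
    return e_in / e_out


def parse_network(path) -> nx.Graph:
    """Read an undirected simple graph from a two-column edge list.

    Whitespace/TSV separated, ``#`` comments allowed; duplicate edges are
    collapsed and self-loops dropped with a warning.
    """
    g = nx.Graph()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        u, v = parts
        if u == v:
            logger.warning("%s:%d: self-loop %s dropped", path, lineno, u)
            continue
        g.add_edge(u, v)
    return g


def identify_cores(
    aplus_reordered: CoClusterMatrix,
    network: Optional[nx.Graph] = None,
) -> list:
    """Find, filter, and (optionally) cohesion-annotate cores in one call."""
    sums = block_sums(aplus_reordered.values)
    cores = find_cores(aplus_reordered)
    kept = filter_cores(cores, sums, aplus_reordered.zbar, aplus_reordered.n)
    if network is not None:
        kept = [replace(c, cohesion=cohesion(c.members, network)) for c in kept]
    return kept


def cores_tsv(cores: Sequence) -> str:
    lines = ["core_id\tp\tq\tsize\tdensity\texpected_density\tcohesion\tmembers"]
    for idx, c in enumerate(cores):
        coh = "" if c.cohesion is None else fmt(c.cohesion)
        lines.append(
            f"c{idx}\t{c.p}\t{c.q}\t{c.size}\t{fmt(c.density)}\t"
            f"{fmt(c.expected_density)}\t{coh}\t{','.join(c.members)}"
        )
    return "\n".join(lines) + "\n"
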