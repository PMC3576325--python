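"""Co-cluster matrices, pair signatures, the pairs table, and base masking.

For a single clustering K over n items the binary co-cluster matrix A^K has
a_ij = 1 iff items i and j (i ≠ j) share at least one module in K — a pair
sitting in two overlapping modules still scores 1, not 2.  Summing A^K over
the k clusterings of an ensemble gives A⁺, whose entries range 0..k: high
values mark item pairs that co-cluster almost everywhere, low values mark
pairs that co-cluster in few clusterings and are more likely artifacts of a
single algorithm or parameter choice.

The *signature* of a pair (u, v) is the k-long 0/1 vector saying in which
clusterings the pair co-clustered; its sum equals the A⁺ entry.  A *base*
clustering (a trusted ground truth) masks A⁺ down to the pairs it itself
co-clusters, so renderers can gray out everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ensemble import Clustering, Ensemble

__all__ = [
    "CoClusterMatrix",
    "Signature",
    "BaseMask",
    "cocluster_single",
    "aggregate",
    "signature",
    "pairs_table",
    "base_mask",
    "permute",
    "matrix_tsv",
    "pairs_tsv",
]


@dataclass(frozen=True)
class CoClusterMatrix:
    """Symmetric n×n integer matrix A⁺ over an explicit item ordering.

    ``k`` is the number of clusterings summed and ``zbar`` the number of
    non-zero strict-upper-triangle cells (unordered co-clustered pairs).
    """

    items: tuple
    values: np.ndarray
    k: int

    def __post_init__(self):
        v = self.values
        n = len(self.items)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match item list")
        if not np.array_equal(v, v.T):
            raise ValueError("co-cluster matrix must be symmetric")
        if np.any(np.diagonal(v) != 0):
            raise ValueError("co-cluster matrix diagonal must be zero")
        if v.min() < 0 or v.max() > self.k:
            raise ValueError("co-cluster values must lie in [0, k]")

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def zbar(self) -> int:
        """Number of non-zero cells in the strict upper triangle."""
        iu = np.triu_indices(self.n, k=1)
        return int(np.count_nonzero(self.values[iu]))

    def index(self) -> dict:
        return {u: i for i, u in enumerate(self.items)}


@dataclass(frozen=True)
class Signature:
    """Per-pair co-clustering record: bits in ensemble clustering order."""

    item_u: str
    item_v: str
    bits: tuple

    @property
    def count(self) -> int:
        return sum(self.bits)

    def as_string(self) -> str:
        return "".join(str(b) for b in self.bits)


@dataclass(frozen=True)
class BaseMask:
    """Pairs (as index pairs i<j) co-clustered in the designated base clustering."""

    base: str
    keep: frozenset


def cocluster_single(clustering: Clustering, items: Sequence) -> np.ndarray:
    """Binary co-cluster matrix of one clustering over the given item order."""
    if len(set(items)) != len(items):
        raise ValueError("item list must be unique")
    index = {u: i for i, u in enumerate(items)}
    n = len(items)
    a = np.zeros((n, n), dtype=np.int64)
    for m in clustering.modules:
        idx = np.fromiter((index[u] for u in m.members if u in index), dtype=np.intp)
        if idx.size:
            a[np.ix_(idx, idx)] = 1  # membership in >1 shared module still counts once
    np.fill_diagonal(a, 0)
    return a


def aggregate(ensemble: Ensemble) -> CoClusterMatrix:
    """Summed co-cluster matrix A⁺ = Σ_t A^{K_t} in ensemble universe order."""
    items = tuple(ensemble.universe)
    total = np.zeros((len(items), len(items)), dtype=np.int64)
    for c in ensemble.clusterings:
        total += cocluster_single(c, items)
    return CoClusterMatrix(items=items, values=total, k=ensemble.k)


def signature(ensemble: Ensemble, u: str, v: str) -> Signature:
    """Signature of the pair (u, v): bit t is 1 iff they share a module in K_t."""
    if u == v:
        raise ValueError("signature needs two distinct items")
    uni = set(ensemble.universe)
    for item in (u, v):
        if item not in uni:
            raise KeyError(f"unknown item ID {item!r}")
    bits = []
    for c in ensemble.clusterings:
        bits.append(int(any(u in m.members and v in m.members for m in c.modules)))
    return Signature(item_u=u, item_v=v, bits=tuple(bits))


def _parse_pattern(pattern: str, k: int) -> tuple:
    if len(pattern) != k or any(ch not in "01*" for ch in pattern):
        raise ValueError(
            f"pattern must be {k} characters over {{0,1,*}}, got {pattern!r}"
        )
    return tuple(pattern)


def pairs_table(
    ensemble: Ensemble,
    pattern: Optional[str] = None,
    min_count: int = 1,
) -> list:
    """All co-clustered pairs as signatures, filtered by pattern and count.

    ``pattern`` is a k-long string over {0,1,*} matched positionally against
    the signature bits ('*' matches either).  Pairs must co-cluster at least
    ``max(min_count, 1)`` times, so the unfiltered table is exactly the
    non-zero upper-triangle support of A⁺.  Rows are ordered by item pair.
    """
    k = ensemble.k
    pat = _parse_pattern(pattern, k) if pattern is not None else None
    min_count = max(min_count, 1)
    items = ensemble.universe
    index = {u: i for i, u in enumerate(items)}
    stacked = np.stack(
        [cocluster_single(c, items) for c in ensemble.clusterings], axis=0
    )
    counts = stacked.sum(axis=0)
    out = []
    iu, ju = np.nonzero(np.triu(counts, k=1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        bits = tuple(int(b) for b in stacked[:, i, j])
        if sum(bits) < min_count:
            continue
        if pat is not None and any(
            p != "*" and int(p) != b for p, b in zip(pat, bits)
        ):
            continue
        out.append(Signature(item_u=items[i], item_v=items[j], bits=bits))
    return out


def sort_pairs(rows, by: str = "items") -> list:
    """Sort signature rows by 'items', 'count' (desc), or 'signature'.

    'signature' interprets the bit vector as a binary number with the
    most recent clustering least significant.
    """
    if by == "items":
        key = lambda s: (s.item_u, s.item_v)
    elif by == "count":
        key = lambda s: (-s.count, s.item_u, s.item_v)
    elif by == "signature":
        key = lambda s: (
            -sum(b << t for t, b in enumerate(reversed(s.bits))),
            s.item_u,
            s.item_v,
        )
    else:
        raise ValueError(f"unknown sort key {by!r}")
    return sorted(rows, key=key)


def base_mask(aplus: CoClusterMatrix, base: Clustering) -> BaseMask:
    """Index pairs (i<j) co-clustered in the base clustering.

    Renderers keep these cells colored and gray out all other non-zero cells
    of A⁺, focusing attention on agreement with the trusted clustering.
    """
    index = aplus.index()
    unknown = base.clustered_items - set(aplus.items)
    if unknown:
        raise ValueError(f"base clustering has items outside the universe: {sorted(unknown)[:5]}")
    b = cocluster_single(base, aplus.items)
    iu, ju = np.nonzero(np.triu(b, k=1))
    return BaseMask(base=base.name, keep=frozenset(zip(iu.tolist(), ju.tolist())))


def permute(aplus: CoClusterMatrix, order: Sequence) -> CoClusterMatrix:
    """Symmetrically reorder rows/columns; ``order[ℓ]`` = item index at position ℓ."""
    idx = np.asarray(order, dtype=np.intp)
    if sorted(idx.tolist()) != list(range(aplus.n)):
        raise ValueError("order must be a permutation of range(n)")
    return CoClusterMatrix(
        items=tuple(aplus.items[i] for i in idx),
        values=aplus.values[np.ix_(idx, idx)],
        k=aplus.k,
    )


def matrix_tsv(aplus: CoClusterMatrix) -> str:
    """A⁺ as a TSV matrix with item-ID header row and column."""
    lines = ["\t" + "\t".join(aplus.items)]
    for i, u in enumerate(aplus.items):
        lines.append(u + "\t" + "\t".join(str(int(x)) for x in aplus.values[i]))
    return "\n".join(lines) + "\n"


def pairs_tsv(rows) -> str:
    lines = ["item_u\titem_v\tcount\tsignature"]
    for s in rows:
        lines.append(f"{s.item_u}\t{s.item_v}\t{s.count}\t{s.as_string()}")
    return "\n".join(lines) + "\n"
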