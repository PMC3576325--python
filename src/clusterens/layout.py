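"""Ordering heuristics for the parallel-partitions view.

Each clustering is drawn as a horizontal band of module blocks; ribbons
connect copies of the same item in vertically adjacent bands.  Crossings
stay low when (a) similar clusterings sit next to each other and (b) item
order within bands follows the co-cluster matrix ordering.  Three
heuristics implement this:

* band order — greedy chain seeded with the most similar clustering pair,
  then repeatedly appending the clustering most similar to the last one
  added;
* module order within a band — ascending displacement rank
  d(m) = Σ_{u∈m} i(u), where i(u) is the item's matrix column;
* item order within a module — ascending matrix column.

The grab bag (items the clustering left unassigned) is always the trailing
block of a band.  Overlapping modules are laid out by duplicating an item
in every module it occurs in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import GRAB_BAG_LABEL, Clustering, Ensemble, grab_bag
from .reordering import Ordering
from .similarity import DISTANCE_METRICS, compare_clusterings

__all__ = [
    "PlacedModule",
    "Band",
    "BandLayout",
    "order_bands",
    "rank_modules",
    "order_items_within_module",
    "build_layout",
    "layout_tsv",
]

#: gap between adjacent module blocks within a band, in item units
MODULE_GAP = 1


@dataclass(frozen=True)
class PlacedModule:
    label: str
    items: tuple  # ordered item IDs
    start: int  # offset within the band, in item units
    is_grab_bag: bool = False

    @property
    def width(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class Band:
    name: str
    modules: tuple  # PlacedModule, grab bag last if present

    @property
    def width(self) -> int:
        last = self.modules[-1]
        return last.start + last.width


@dataclass(frozen=True)
class BandLayout:
    bands: tuple  # in vertical order

    @property
    def band_order(self) -> tuple:
        return tuple(b.name for b in self.bands)


def _similarity_for_ordering(ensemble, a, b, metric):
    v = compare_clusterings(
        ensemble.clusterings[a], ensemble.clusterings[b], metric, ensemble.universe
    )
    return -v if metric in DISTANCE_METRICS else v


def order_bands(ensemble: Ensemble, metric: str = "jaccard") -> list:
    """Greedy band order: seed with the most similar pair, then chain.

    The seed pair is oriented so that the member with the higher best
    similarity to any remaining clustering becomes the chain's tail; each
    subsequent pick maximizes similarity to the last clustering added.
    Ties resolve lexicographically by clustering name, so the order is
    deterministic.
    """
    k = ensemble.k
    names = [c.name for c in ensemble.clusterings]
    if k == 1:
        return list(names)
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(i):
            sim[i, j] = sim[j, i] = _similarity_for_ordering(ensemble, i, j, metric)
    # most similar pair, ties by name pair
    pairs = sorted(
        ((i, j) for i in range(k) for j in range(i)),
        key=lambda ij: (-sim[ij[0], ij[1]], min(names[ij[0]], names[ij[1]]),
                        max(names[ij[0]], names[ij[1]])),
    )
    a, b = pairs[0]
    remaining = [t for t in range(k) if t not in (a, b)]
    if remaining:
        def best_outside(x):
            return max(sim[x, r] for r in remaining)
        # orient: member with the higher best similarity to the rest goes last
        if best_outside(a) > best_outside(b) or (
            best_outside(a) == best_outside(b) and names[a] < names[b]
        ):
            chain = [b, a]
        else:
            chain = [a, b]
    else:
        chain = sorted((a, b), key=lambda t: names[t])
    while remaining:
        last = chain[-1]
        remaining.sort(key=lambda t: (-sim[last, t], names[t]))
        chain.append(remaining.pop(0))
    return [names[t] for t in chain]


def _column_index(matrix_order: Ordering, items) -> dict:
    """Map item ID → matrix column position (requires matching lengths)."""
    return {u: matrix_order.positions[i] for i, u in enumerate(items)}


def rank_modules(clustering: Clustering, col_of: dict) -> list:
    """Modules sorted by ascending displacement rank d(m) = Σ_{u∈m} i(u).

    ``col_of`` maps item ID → matrix column.  Items missing from the matrix
    order contribute a past-the-end column.  Ties break by label.
    """
    n = len(col_of)
    ranked = sorted(
        clustering.modules,
        key=lambda m: (sum(col_of.get(u, n) for u in m.members), m.label),
    )
    return list(ranked)


def order_items_within_module(module_members, col_of: dict) -> list:
    """Members sorted by matrix column; unknown items go last (by ID)."""
    n = len(col_of)
    return sorted(module_members, key=lambda u: (col_of.get(u, n), u))


def build_layout(
    ensemble: Ensemble,
    matrix_order: Ordering,
    metric: str = "jaccard",
) -> BandLayout:
    """Full parallel-partitions layout: band order, module order, item order.

    Every universe item appears in a band once per module membership
    (duplicated when modules overlap); leftover items form a trailing
    grab-bag block.  Module extents are consecutive with a fixed gap of
    ``MODULE_GAP`` between blocks.
    """
    col_of = _column_index(matrix_order, ensemble.universe)
    bands = []
    for name in order_bands(ensemble, metric):
        clustering = ensemble[name]
        placed = []
        offset = 0
        for m in rank_modules(clustering, col_of):
            items = tuple(order_items_within_module(m.members, col_of))
            placed.append(PlacedModule(label=m.label, items=items, start=offset))
            offset += len(items) + MODULE_GAP
        bag = grab_bag(clustering, ensemble.universe)
        if bag:
            items = tuple(order_items_within_module(bag, col_of))
            placed.append(
                PlacedModule(
                    label=GRAB_BAG_LABEL, items=items, start=offset, is_grab_bag=True
                )
            )
        bands.append(Band(name=name, modules=tuple(placed)))
    return BandLayout(bands=tuple(bands))


def layout_tsv(layout: BandLayout) -> str:
    lines = ["band\tband_position\tmodule_label\titem\titem_position"]
    for b_idx, band in enumerate(layout.bands):
        for pm in band.modules:
            for off, item in enumerate(pm.items):
                lines.append(
                    f"{band.name}\t{b_idx}\t{pm.label}\t{item}\t{pm.start + off}"
                )
    return "\n".join(lines) + "\n"
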