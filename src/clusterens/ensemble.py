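"""Data model for clusterings and ensembles, module-file I/O, and overview statistics.

A *clustering* is a collection of *modules* (groups of item IDs — genes,
proteins, sequence IDs) as produced by a graph- or expression-clustering
algorithm.  Modules may overlap and a clustering may cover only part of the
item universe; both states are first-class here, not errors.  An *ensemble*
is an ordered collection of clusterings over the union of their items.

Module files use the MCL dialect: one clustering per file, one module per
line, item IDs separated by whitespace.  Lines starting with ``#`` and blank
lines are ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Module",
    "Clustering",
    "Ensemble",
    "ClusteringStats",
    "ClusteringInputError",
    "parse_module_file",
    "parse_module_lines",
    "load_ensemble",
    "write_module_file",
    "grab_bag",
    "clustering_entropy",
    "overview_stats",
    "filter_min_size",
    "stats_tsv",
]

GRAB_BAG_LABEL = "grab_bag"


class ClusteringInputError(ValueError):
    """Raised for malformed or empty clustering input."""


@dataclass(frozen=True)
class Module:
    """A group of co-clustered items.

    Parameters
    ----------
    label : str
        Module name; auto-assigned ``m<index>`` when the file gives none.
    members : frozenset of str
        Non-empty set of item IDs.
    """

    label: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ClusteringInputError(f"module {self.label!r} is empty")

    def __len__(self):
        return len(self.members)


@dataclass(frozen=True)
class Clustering:
    """An ordered list of modules produced by one algorithm run."""

    name: str
    modules: tuple

    def __post_init__(self):
        if not self.modules:
            raise ClusteringInputError(f"clustering {self.name!r} has no modules")

    @property
    def clustered_items(self) -> frozenset:
        """Union of all module members."""
        out = set()
        for m in self.modules:
            out |= m.members
        return frozenset(out)

    @property
    def has_overlap(self) -> bool:
        total = sum(len(m) for m in self.modules)
        return total > len(self.clustered_items)

    def multi_module_items(self) -> frozenset:
        """Items assigned to more than one module."""
        seen, multi = set(), set()
        for m in self.modules:
            multi |= seen & m.members
            seen |= m.members
        return frozenset(multi)


@dataclass(frozen=True)
class Ensemble:
    """Ordered collection of k clusterings plus the item universe.

    The universe is the first-appearance-ordered union of all items across
    the clusterings; its order is the canonical item order for co-cluster
    matrices, and the clustering order defines signature positions.
    """

    clusterings: tuple
    universe: tuple

    def __post_init__(self):
        if not self.clusterings:
            raise ClusteringInputError("ensemble needs at least one clustering")
        names = [c.name for c in self.clusterings]
        if len(set(names)) != len(names):
            raise ClusteringInputError(f"duplicate clustering names: {names}")
        if len(set(self.universe)) != len(self.universe):
            raise ClusteringInputError("universe contains duplicate items")

    @property
    def k(self) -> int:
        return len(self.clusterings)

    @property
    def n(self) -> int:
        return len(self.universe)

    def __getitem__(self, name: str) -> Clustering:
        for c in self.clusterings:
            if c.name == name:
                return c
        raise KeyError(name)

    @classmethod
    def from_clusterings(cls, clusterings: Iterable[Clustering]) -> "Ensemble":
        clusterings = tuple(clusterings)
        seen: dict = {}
        for c in clusterings:
            for m in c.modules:
                # sorted within a module for a deterministic first-appearance order
                for item in sorted(m.members):
                    seen.setdefault(item, None)
        return cls(clusterings=clusterings, universe=tuple(seen))


@dataclass(frozen=True)
class ClusteringStats:
    """Per-clustering overview statistics."""

    name: str
    n_modules: int
    avg_module_size: float
    n_items_clustered: int
    entropy: float  # bits
    pct_overlapping: float  # % of clustered items in >1 module
    has_overlap: bool


def parse_module_lines(lines: Iterable[str], name: str) -> Clustering:
    """Build a clustering from an iterable of module lines (MCL dialect)."""
    modules = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        ids = line.split()
        unique = list(dict.fromkeys(ids))
        if len(unique) < len(ids):
            logger.warning(
                "clustering %s, module m%d: %d duplicate item ID(s) dropped",
                name, len(modules), len(ids) - len(unique),
            )
        modules.append(Module(label=f"m{len(modules)}", members=frozenset(unique)))
    if not modules:
        raise ClusteringInputError(f"clustering {name!r}: no modules found")
    return Clustering(name=name, modules=tuple(modules))


def parse_module_file(path, name: str | None = None) -> Clustering:
    """Parse one module file (one module per line, whitespace-separated IDs)."""
    path = Path(path)
    if name is None:
        name = path.stem
    try:
        text = path.read_text()
    except OSError as exc:
        raise ClusteringInputError(f"cannot read {path}: {exc}") from exc
    return parse_module_lines(text.splitlines(), name)


def write_module_file(clustering: Clustering, path) -> None:
    """Serialize a clustering back to the module-file dialect (sorted IDs per line)."""
    lines = [" ".join(sorted(m.members)) for m in clustering.modules]
    Path(path).write_text("\n".join(lines) + "\n")


def load_ensemble(paths: Sequence) -> Ensemble:
    """Load an ensemble from module files, one clustering per file, in input order."""
    if not paths:
        raise ClusteringInputError("no module files given")
    clusterings = []
    for p in paths:
        clusterings.append(parse_module_file(p))
    return Ensemble.from_clusterings(clusterings)


def grab_bag(clustering: Clustering, universe: Sequence) -> frozenset:
    """Items of the universe that the clustering left unassigned (may be empty)."""
    return frozenset(universe) - clustering.clustered_items


def clustering_entropy(clustering: Clustering) -> float:
    """Shannon entropy of the module-size distribution, in bits.

    H = −Σ_i (|m_i|/N)·log2(|m_i|/N) with N = Σ_i |m_i| (membership slots).
    An item in several modules contributes one slot per membership, so for
    overlapping clusterings this overestimates the partition entropy.
    """
    sizes = [len(m) for m in clustering.modules]
    total = sum(sizes)
    h = 0.0
    for s in sizes:
        p = s / total
        h -= p * math.log2(p)
    return h


def overview_stats(ensemble: Ensemble) -> list:
    """One :class:`ClusteringStats` record per clustering, in ensemble order."""
    out = []
    for c in ensemble.clusterings:
        slots = sum(len(m) for m in c.modules)
        clustered = c.clustered_items
        multi = c.multi_module_items()
        out.append(
            ClusteringStats(
                name=c.name,
                n_modules=len(c.modules),
                avg_module_size=slots / len(c.modules),
                n_items_clustered=len(clustered),
                entropy=clustering_entropy(c),
                pct_overlapping=100.0 * len(multi) / len(clustered),
                has_overlap=c.has_overlap,
            )
        )
    return out


def filter_min_size(clustering: Clustering, min_size: int) -> Clustering:
    """Drop modules smaller than ``min_size`` items (labels are preserved)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = tuple(m for m in clustering.modules if len(m) >= min_size)
    if not kept:
        raise ClusteringInputError(
            f"clustering {clustering.name!r}: no modules of size >= {min_size}"
        )
    return Clustering(name=clustering.name, modules=kept)


def stats_tsv(stats: Iterable[ClusteringStats]) -> str:
    """Overview statistics as a TSV table (6 significant digits)."""
    from ._format import fmt

    header = ("clustering\tn_modules\tavg_module_size\tn_items\tentropy_bits\t"
              "pct_overlapping\thas_overlap")
    rows = [header]
    for s in stats:
        rows.append(
            f"{s.name}\t{s.n_modules}\t{fmt(s.avg_module_size)}\t{s.n_items_clustered}"
            f"\t{fmt(s.entropy)}\t{fmt(s.pct_overlapping)}\t{str(s.has_overlap).lower()}"
        )
    return "\n".join(rows) + "\n"
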