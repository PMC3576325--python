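"""Synthetic ensembles with planted co-clustered cores, and brute-force
reference oracles.

The generator emulates the situations the rest of the package is built to
expose: groups of items that co-cluster intact across most of an ensemble
(planted cores), surrounded by randomly partitioned background items, with
optional per-clustering noise, partial coverage, and module overlap.  The
ground truth (which items form which planted group) is returned alongside
the ensemble, so recovery can be scored.

The oracles are deliberately naive, independent code paths — an O(n²) pair
loop for the pair-counting metrics, an O(n⁴) quadruple loop for block sums,
exhaustive enumeration of all 2^(n−1) contiguous partitions, and an n!
search for the linear assignment problem — usable only at small n, and
never sharing helpers with the fast implementations they check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .ensemble import Clustering, Ensemble, Module

__all__ = [
    "PlantedEnsembleSpec",
    "generate_ensemble",
    "oracle_pair_metric",
    "oracle_block_sums",
    "oracle_best_partition",
    "oracle_lap",
]

#: Default study conditions: five disjoint planted groups of sizes 5–20,
#: each intact in 6–8 of k = 8 clusterings, 5% reassignment noise, full
#: coverage, no overlap, over 120 items.
DEFAULT_GROUPS = ((8, 7), (12, 6), (20, 8), (5, 6), (15, 7))


def fit_groups(n_items: int, k: int) -> tuple:
    """Planted groups following the default size/support pattern, scaled so
    they occupy about half of ``n_items`` (supports clipped to k)."""
    groups = []
    budget = n_items // 2
    for size, support in itertools.cycle(DEFAULT_GROUPS):
        if size > budget:
            break
        groups.append((size, min(support, k)))
        budget -= size
    return tuple(groups)


@dataclass(frozen=True)
class PlantedEnsembleSpec:
    """Parameters of a planted-core ensemble.

    ``groups`` is a list of (size, support) pairs: each group of that size
    appears as an intact module in exactly ``support`` of the k
    clusterings.  ``noise_rate`` is the probability that a background item
    is reassigned to another background module; ``coverage`` the fraction
    of background items a clustering assigns at all; ``overlap_rate`` the
    probability that a clustered item is additionally placed in a second
    (background) module.
    """

    n_items: int = 120
    k: int = 8
    groups: tuple = DEFAULT_GROUPS
    noise_rate: float = 0.05
    coverage: float = 1.0
    overlap_rate: float = 0.0
    bg_module_size: tuple = (3, 15)
    seed: int = 0

    def __post_init__(self):
        if sum(size for size, _ in self.groups) > self.n_items:
            raise ValueError("planted group sizes exceed n_items")
        for rate in (self.noise_rate, self.coverage, self.overlap_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for _, support in self.groups:
            if not 0 <= support <= self.k:
                raise ValueError("group support must lie in [0, k]")


def generate_ensemble(spec: PlantedEnsembleSpec):
    """Generate (Ensemble, ground-truth groups) deterministically from the seed.

    Ground truth is a dict ``group label → frozenset of item IDs``.  Each
    planted group appears as an intact module in exactly ``support``
    clusterings; noise, coverage, and overlap are applied only to items
    outside a clustering's intact planted modules, so intactness is exact.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(max(spec.n_items - 1, 1)))
    items = [f"v{i:0{width}d}" for i in range(spec.n_items)]
    truth = {}
    cursor = 0
    supports = []
    for g_idx, (size, support) in enumerate(spec.groups):
        truth[f"g{g_idx}"] = frozenset(items[cursor : cursor + size])
        supports.append(
            set(rng.choice(spec.k, size=support, replace=False).tolist())
        )
        cursor += size

    clusterings = []
    for t in range(spec.k):
        intact = [
            sorted(truth[f"g{g_idx}"])
            for g_idx in range(len(spec.groups))
            if t in supports[g_idx]
        ]
        covered = set().union(*map(set, intact)) if intact else set()
        free = [u for u in items if u not in covered]
        rng.shuffle(free)
        # random background partition of the free items
        background = []
        lo, hi = spec.bg_module_size
        pos = 0
        while pos < len(free):
            size = int(rng.integers(lo, hi + 1))
            background.append(free[pos : pos + size])
            pos += size
        # noise: reassign background items between background modules
        if spec.noise_rate > 0 and len(background) > 1:
            for m_idx, mod in enumerate(background):
                for u in list(mod):
                    if rng.random() < spec.noise_rate and len(mod) > 1:
                        target = int(rng.integers(len(background) - 1))
                        if target >= m_idx:
                            target += 1
                        mod.remove(u)
                        background[target].append(u)
        # coverage: drop background items into the grab bag
        if spec.coverage < 1.0:
            n_drop = round((1.0 - spec.coverage) * len(free))
            droppable = [(m_idx, u) for m_idx, mod in enumerate(background) for u in mod]
            order = rng.permutation(len(droppable))
            for idx in order[:n_drop]:
                m_idx, u = droppable[int(idx)]
                if u in background[m_idx]:
                    background[m_idx].remove(u)
        background = [sorted(mod) for mod in background if mod]
        # overlap: duplicate clustered items into a second background module
        if spec.overlap_rate > 0 and background:
            clustered = [u for mod in intact for u in mod] + [
                u for mod in background for u in mod
            ]
            for u in clustered:
                if rng.random() < spec.overlap_rate:
                    target = int(rng.integers(len(background)))
                    if u not in background[target]:
                        background[target].append(u)
        modules = [frozenset(m) for m in intact] + [
            frozenset(m) for m in background
        ]
        if not modules:
            modules = [frozenset(items)]
        clusterings.append(
            Clustering(
                name=f"K{t}",
                modules=tuple(
                    Module(label=f"m{i}", members=m) for i, m in enumerate(modules)
                ),
            )
        )
    return Ensemble.from_clusterings(clusterings), truth


# ---------------------------------------------------------------------------
# brute-force oracles (independent reference implementations, small n only)
# ---------------------------------------------------------------------------


def _co(clustering: Clustering, u, v) -> bool:
    return any(u in m.members and v in m.members for m in clustering.modules)


def oracle_pair_metric(c1, c2, metric, universe) -> float:
    """Pair-counting metric by direct enumeration of all item pairs (n ≤ 200).

    Unclustered items co-cluster with nothing, matching the singleton
    policy of the fast path.
    """
    items = list(universe)
    if len(items) > 200:
        raise ValueError("oracle limited to n <= 200")
    n11 = n10 = n01 = n00 = 0
    for a, b in itertools.combinations(items, 2):
        in1, in2 = _co(c1, a, b), _co(c2, a, b)
        if in1 and in2:
            n11 += 1
        elif in1:
            n10 += 1
        elif in2:
            n01 += 1
        else:
            n00 += 1
    n = len(items)
    if metric == "jaccard":
        denom = n11 + n10 + n01
        return n11 / denom if denom else 1.0
    if metric == "rand":
        total = n11 + n10 + n01 + n00
        return (n11 + n00) / total if total else 1.0
    if metric == "fowlkes_mallows":
        m1, m2 = n11 + n10, n11 + n01
        if m1 == 0 and m2 == 0:
            return 1.0
        if m1 == 0 or m2 == 0:
            return 0.0
        return n11 / math.sqrt(m1 * m2)
    if metric == "mirkin":
        return 2.0 * (n10 + n01) / (n * n) if n else 0.0
    raise ValueError(f"oracle does not implement {metric!r}")


def oracle_block_sums(values: np.ndarray) -> np.ndarray:
    """s(p,q) by brute-force O(n⁴) summation; returns n×n array, 0-based (n ≤ 20)."""
    a = np.asarray(values, dtype=float)
    n = a.shape[0]
    if n > 20:
        raise ValueError("oracle limited to n <= 20")
    s = np.zeros((n, n))
    for p in range(n):
        for q in range(p, n):
            acc = 0.0
            for i in range(p, q):
                for j in range(i + 1, q + 1):
                    acc += a[i, j]
            s[p, q] = acc
    return s


def oracle_best_partition(values: np.ndarray):
    """Exhaustive search over all 2^(n−1) contiguous partitions (n ≤ 12).

    Returns (best summed density, blocks as 1-based (p, q) tuples); density
    uses the vertex-count denominator h = q−p+1.
    """
    a = np.asarray(values, dtype=float)
    n = a.shape[0]
    if n > 12:
        raise ValueError("oracle limited to n <= 12")

    def block_density(p, q):  # 0-based inclusive
        acc = 0.0
        for i in range(p, q):
            for j in range(i + 1, q + 1):
                acc += a[i, j]
        return acc / (q - p + 1)

    best_score, best_blocks = -math.inf, None
    for mask in range(1 << (n - 1)) if n > 1 else [0]:
        cuts = [i + 1 for i in range(n - 1) if mask >> i & 1]
        bounds = list(zip([0] + cuts, [c - 1 for c in cuts] + [n - 1]))
        score = sum(block_density(p, q) for p, q in bounds)
        if score > best_score + 1e-12:
            best_score = score
            best_blocks = [(p + 1, q + 1) for p, q in bounds]
    return best_score, best_blocks


def oracle_lap(weights: np.ndarray):
    """Exhaustive n! linear assignment (n ≤ 7): returns (min cost, positions)."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if n > 7:
        raise ValueError("oracle limited to n <= 7")
    best_cost, best_perm = math.inf, None
    for perm in itertools.permutations(range(n)):
        cost = sum(w[i, perm[i]] for i in range(n))
        if cost < best_cost - 1e-12:
            best_cost, best_perm = cost, perm
    return best_cost, best_perm
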