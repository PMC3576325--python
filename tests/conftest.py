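import numpy as np
import pytest

from clusterens.ensemble import Clustering, Ensemble, Module


def make_clustering(name, *module_sets):
    return Clustering(
        name=name,
        modules=tuple(
            Module(label=f"m{i}", members=frozenset(s))
            for i, s in enumerate(module_sets)
        ),
    )


def random_partition(rng, items, max_modules=5):
    """Random full-coverage, non-overlapping clustering over the items."""
    items = list(items)
    rng.shuffle(items)
    n_mod = int(rng.integers(1, min(max_modules, len(items)) + 1))
    cuts = sorted(rng.choice(np.arange(1, len(items)), size=n_mod - 1, replace=False).tolist()) if n_mod > 1 else []
    bounds = zip([0] + cuts, cuts + [len(items)])
    return [set(items[a:b]) for a, b in bounds]


def random_clustering(rng, items, name, max_modules=5, coverage=1.0, overlap=0.0):
    """Random clustering, optionally partial-coverage and overlapping."""
    mods = random_partition(rng, items, max_modules)
    if coverage < 1.0:
        keep = int(round(coverage * len(items)))
        kept = set(list(items)[:0])
        pool = [u for m in mods for u in m]
        rng.shuffle(pool)
        kept = set(pool[:keep])
        mods = [m & kept for m in mods]
        mods = [m for m in mods if m]
        if not mods:
            mods = [set(pool[:1])]
    if overlap > 0.0:
        all_items = [u for m in mods for u in m]
        for u in all_items:
            if rng.random() < overlap and len(mods) > 1:
                mods[int(rng.integers(len(mods)))].add(u)
    return make_clustering(name, *mods)


@pytest.fixture
def toy_pair():
    """The worked pair: K1 = {a,b},{c,d}; K2 = {a,b,c},{d}."""
    c1 = make_clustering("K1", {"a", "b"}, {"c", "d"})
    c2 = make_clustering("K2", {"a", "b", "c"}, {"d"})
    return c1, c2, ["a", "b", "c", "d"]


@pytest.fixture
def toy_ensemble(toy_pair):
    c1, c2, _ = toy_pair
    return Ensemble.from_clusterings([c1, c2])


@pytest.fixture
def identical_triple():
    """Three identical clusterings of two modules (block-diagonal regime)."""
    mods = ({"a", "b", "c"}, {"d", "e"})
    return Ensemble.from_clusterings(
        [make_clustering(f"K{i}", *mods) for i in range(3)]
    )
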