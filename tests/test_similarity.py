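import math

import numpy as np
import pytest

from clusterens.ensemble import Ensemble
from clusterens.similarity import (
    METRICS,
    compare_clusterings,
    ladder,
    module_pair_table,
    pair_counts,
)
from clusterens.synthetic import oracle_pair_metric

from conftest import make_clustering, random_clustering

PAIR_METRICS = ("jaccard", "mirkin", "rand", "fowlkes_mallows")


class TestPairCounts:
    def test_worked_example(self, toy_pair):
        c1, c2, universe = toy_pair
        pc = pair_counts(c1, c2, universe)
        assert (pc.n11, pc.n10, pc.n01, pc.n00) == (1, 1, 2, 2)
        assert pc.total == 6

    def test_identical_clusterings_no_disagreement(self, toy_pair):
        c1, _, universe = toy_pair
        pc = pair_counts(c1, c1, universe)
        assert pc.n10 == pc.n01 == 0

    def test_all_singletons(self):
        c = make_clustering("s", {"a"}, {"b"}, {"c"})
        pc = pair_counts(c, c, ["a", "b", "c"])
        assert pc.n11 == 0 and pc.n00 == 3

    def test_counts_sum_to_choose2(self, toy_pair):
        c1, c2, universe = toy_pair
        pc = pair_counts(c1, c2, universe)
        n = len(universe)
        assert pc.total == n * (n - 1) // 2


class TestMetricValues:
    def test_jaccard_worked_example(self, toy_pair):
        c1, c2, universe = toy_pair
        assert compare_clusterings(c1, c2, "jaccard", universe) == pytest.approx(0.25)

    @pytest.mark.parametrize("metric,expected", [
        ("jaccard", 1.0), ("rand", 1.0), ("fowlkes_mallows", 1.0),
        ("purity", 1.0), ("inverse_purity", 1.0), ("f_measure", 1.0),
        ("mirkin", 0.0), ("variation_of_information", 0.0),
    ])
    def test_identity_values(self, toy_pair, metric, expected):
        c1, _, universe = toy_pair
        v = compare_clusterings(c1, c1, metric, universe)
        assert v == pytest.approx(expected, abs=1e-12)

    def test_unknown_metric_rejected(self, toy_pair):
        c1, c2, universe = toy_pair
        with pytest.raises(ValueError, match="unknown metric"):
            compare_clusterings(c1, c2, "nope", universe)

    @pytest.mark.parametrize("metric", METRICS)
    def test_ranges(self, metric):
        rng = np.random.default_rng(7)
        items = [f"i{x}" for x in range(20)]
        for trial in range(10):
            c1 = random_clustering(rng, items, "A")
            c2 = random_clustering(rng, items, "B")
            v = compare_clusterings(c1, c2, metric, items)
            if metric == "variation_of_information":
                assert 0.0 <= v <= math.log2(len(items)) + 1e-9
            elif metric == "mutual_information":
                assert v >= -1e-12
            else:
                assert -1e-12 <= v <= 1.0 + 1e-12


class TestOracleAgreement:
    """Fast vectorized pair counting vs independent O(n²) enumeration."""

    @pytest.mark.parametrize("metric", PAIR_METRICS)
    def test_random_full_coverage(self, metric):
        rng = np.random.default_rng(11)
        for trial in range(25):
            n = int(rng.integers(4, 30))
            items = [f"i{x}" for x in range(n)]
            c1 = random_clustering(rng, items, "A")
            c2 = random_clustering(rng, items, "B")
            fast = compare_clusterings(c1, c2, metric, items)
            slow = oracle_pair_metric(c1, c2, metric, items)
            assert fast == pytest.approx(slow, abs=1e-12)

    @pytest.mark.parametrize("metric", PAIR_METRICS)
    def test_partial_coverage_and_overlap(self, metric):
        rng = np.random.default_rng(13)
        for trial in range(25):
            n = int(rng.integers(6, 30))
            items = [f"i{x}" for x in range(n)]
            c1 = random_clustering(rng, items, "A", coverage=0.7, overlap=0.2)
            c2 = random_clustering(rng, items, "B", coverage=0.8)
            fast = compare_clusterings(c1, c2, metric, items)
            slow = oracle_pair_metric(c1, c2, metric, items)
            assert fast == pytest.approx(slow, abs=1e-12)


class TestInformationMetrics:
    def test_vi_identity(self):
        """VI = H1 + H2 − 2·MI, with H from the contingency marginals equal
        to the slot entropy for full-coverage partitions."""
        from clusterens.ensemble import clustering_entropy

        rng = np.random.default_rng(5)
        items = [f"i{x}" for x in range(24)]
        for trial in range(20):
            c1 = random_clustering(rng, items, "A")
            c2 = random_clustering(rng, items, "B")
            mi = compare_clusterings(c1, c2, "mutual_information", items)
            vi = compare_clusterings(c1, c2, "variation_of_information", items)
            h1 = clustering_entropy(c1)
            h2 = clustering_entropy(c2)
            assert vi == pytest.approx(h1 + h2 - 2 * mi, abs=1e-9)

    def test_cross_check_sklearn(self):
        """MI (bits) and Rand agree with scikit-learn on full-coverage
        partitions (reference cross-check only)."""
        from sklearn.metrics import mutual_info_score, rand_score

        rng = np.random.default_rng(3)
        items = [f"i{x}" for x in range(30)]
        for trial in range(10):
            c1 = random_clustering(rng, items, "A")
            c2 = random_clustering(rng, items, "B")

            def labels(c):
                lab = {}
                for idx, m in enumerate(c.modules):
                    for u in m.members:
                        lab[u] = idx
                return [lab[u] for u in items]

            l1, l2 = labels(c1), labels(c2)
            mi = compare_clusterings(c1, c2, "mutual_information", items)
            assert mi == pytest.approx(
                mutual_info_score(l1, l2) / math.log(2), abs=1e-9
            )
            rand = compare_clusterings(c1, c2, "rand", items)
            assert rand == pytest.approx(rand_score(l1, l2), abs=1e-9)

    def test_degrading_lowers_jaccard_on_average(self):
        """Random single-item moves away from a reference clustering do not
        increase Jaccard similarity to it, in expectation."""
        rng = np.random.default_rng(17)
        items = [f"i{x}" for x in range(30)]
        base = make_clustering(
            "B", set(items[:10]), set(items[10:20]), set(items[20:])
        )
        diffs = []
        for trial in range(200):
            mods = [set(m.members) for m in base.modules]
            # move one random item to another module
            src = int(rng.integers(len(mods)))
            if len(mods[src]) <= 1 or len(mods) < 2:
                continue
            u = sorted(mods[src])[int(rng.integers(len(mods[src])))]
            dst = int(rng.integers(len(mods) - 1))
            if dst >= src:
                dst += 1
            mods[src].discard(u)
            mods[dst].add(u)
            degraded = make_clustering("D", *[m for m in mods if m])
            diffs.append(
                compare_clusterings(base, degraded, "jaccard", items)
                - compare_clusterings(base, base, "jaccard", items)
            )
        assert np.mean(diffs) < 0


class TestLadder:
    def test_two_clusterings_single_cell(self, toy_ensemble):
        lad = ladder(toy_ensemble, "jaccard")
        assert lad.cell(1, 0) == pytest.approx(0.25)

    def test_identical_triple_identity_values(self, identical_triple):
        lad = ladder(identical_triple, "jaccard")
        for i in range(3):
            for j in range(i):
                assert lad.cell(i, j) == pytest.approx(1.0)

    def test_symmetric_consistency(self):
        rng = np.random.default_rng(23)
        items = [f"i{x}" for x in range(15)]
        cls = [random_clustering(rng, items, f"K{t}") for t in range(4)]
        ens = Ensemble.from_clusterings(cls)
        lad = ladder(ens, "rand")
        for i in range(4):
            for j in range(i):
                swapped = compare_clusterings(
                    cls[j], cls[i], "rand", ens.universe
                )
                assert lad.cell(i, j) == pytest.approx(swapped, abs=1e-12)

    def test_single_clustering_rejected(self):
        ens = Ensemble.from_clusterings([make_clustering("A", {"a", "b"})])
        with pytest.raises(ValueError):
            ladder(ens, "jaccard")


class TestModulePairTable:
    def test_set_algebra(self):
        c1 = make_clustering("A", {"a", "b", "c"})
        c2 = make_clustering("B", {"a", "b", "d"})
        (row,) = module_pair_table(c1, c2)
        assert row.jaccard == pytest.approx(0.5)
        assert row.intersection == frozenset("ab")
        assert row.left_diff == frozenset("c")
        assert row.right_diff == frozenset("d")
        assert len(row.union) == 4

    def test_disjoint_clusterings_empty_table(self):
        c1 = make_clustering("A", {"a", "b"})
        c2 = make_clustering("B", {"c", "d"})
        assert module_pair_table(c1, c2) == []

    def test_jaccard_filter_and_sorting(self):
        c1 = make_clustering("A", {"a", "b", "c"}, {"d", "e"})
        c2 = make_clustering("B", {"a", "b", "c"}, {"d", "x", "y"})
        rows = module_pair_table(c1, c2)
        assert [r.jaccard for r in rows] == sorted(
            (r.jaccard for r in rows), reverse=True
        )
        high = module_pair_table(c1, c2, min_j=0.9)
        assert len(high) == 1 and high[0].jaccard == 1.0

    def test_bad_range_rejected(self):
        c = make_clustering("A", {"a"})
        with pytest.raises(ValueError):
            module_pair_table(c, c, min_j=0.8, max_j=0.2)
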