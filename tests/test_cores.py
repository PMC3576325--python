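import math

import numpy as np
import pytest

from clusterens.cocluster import CoClusterMatrix
from clusterens.cores import (
    block_sums,
    cohesion,
    density,
    expected_density,
    filter_cores,
    find_cores,
    identify_cores,
    parse_network,
)
from clusterens.synthetic import oracle_best_partition, oracle_block_sums


def matrix_from(values, k=None):
    values = np.asarray(values, dtype=np.int64)
    n = values.shape[0]
    k = k if k is not None else max(int(values.max()), 1)
    return CoClusterMatrix(
        items=tuple(f"v{i}" for i in range(n)), values=values, k=k
    )


def random_symmetric(rng, n, high=4):
    a = rng.integers(0, high, size=(n, n))
    a = np.triu(a, 1)
    return a + a.T


class TestBlockSums:
    def test_zero_matrix(self):
        s = block_sums(np.zeros((5, 5)))
        assert np.all(s.s == 0)
        assert s.value(1, 5) == 0.0

    def test_three_by_three(self):
        a = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        s = block_sums(a)
        assert s.value(1, 3) == 6.0
        assert s.value(1, 2) == 2.0
        assert s.value(2, 3) == 2.0
        assert s.value(1, 1) == 0.0

    def test_recurrence_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for trial in range(100):
            n = int(rng.integers(2, 21))
            a = random_symmetric(rng, n)
            fast = block_sums(a)
            slow = oracle_block_sums(a)
            assert np.allclose(fast.s[np.triu_indices(n)], slow[np.triu_indices(n)])

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            block_sums(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestDensity:
    def test_singleton_zero(self):
        s = block_sums(np.ones((4, 4)) - np.eye(4))
        assert density(s, 2, 2) == 0.0

    def test_three_item_full_block(self):
        a = np.full((3, 3), 3.0)
        np.fill_diagonal(a, 0)
        s = block_sums(a)
        assert density(s, 1, 3) == pytest.approx(3.0)  # s=9, h=3

    def test_homogeneity(self):
        rng = np.random.default_rng(5)
        a = random_symmetric(rng, 8).astype(float)
        s1, s2 = block_sums(a), block_sums(2 * a)
        assert density(s2, 2, 6) == pytest.approx(2 * density(s1, 2, 6))


class TestFindCores:
    def test_zero_matrix_single_block(self):
        m = matrix_from(np.zeros((6, 6), dtype=np.int64))
        cores = find_cores(m)
        assert len(cores) == 1
        assert (cores[0].p, cores[0].q) == (1, 6)

    def test_two_planted_blocks_recovered(self):
        a = np.zeros((9, 9), dtype=np.int64)
        a[np.ix_(range(4), range(4))] = 5
        a[np.ix_(range(4, 9), range(4, 9))] = 5
        np.fill_diagonal(a, 0)
        cores = find_cores(matrix_from(a))
        assert [(c.p, c.q) for c in cores] == [(1, 4), (5, 9)]

    def test_partition_covers_all_positions(self):
        rng = np.random.default_rng(11)
        a = random_symmetric(rng, 10)
        cores = find_cores(matrix_from(a))
        bounds = [(c.p, c.q) for c in cores]
        assert bounds[0][0] == 1 and bounds[-1][1] == 10
        for (p1, q1), (p2, q2) in zip(bounds, bounds[1:]):
            assert p2 == q1 + 1

    def test_dp_matches_exhaustive(self):
        rng = np.random.default_rng(21)
        for trial in range(100):
            n = int(rng.integers(2, 13))
            a = random_symmetric(rng, n)
            cores = find_cores(matrix_from(a))
            dp_score = sum(c.density for c in cores)
            best_score, _ = oracle_best_partition(a)
            assert dp_score == pytest.approx(best_score, abs=1e-9)

    def test_members_follow_item_order(self):
        a = np.zeros((4, 4), dtype=np.int64)
        a[0, 1] = a[1, 0] = 2
        m = matrix_from(a)
        cores = find_cores(m)
        all_members = [u for c in cores for u in c.members]
        assert all_members == list(m.items)


class TestExpectedDensity:
    def test_singleton_zero(self):
        a = np.full((5, 5), 2.0)
        np.fill_diagonal(a, 0)
        s = block_sums(a)
        assert expected_density(s, zbar=10, n=5, p=3, q=3) == 0.0

    def test_whole_matrix_equals_global_density(self):
        rng = np.random.default_rng(9)
        a = random_symmetric(rng, 12).astype(float)
        s = block_sums(a)
        zbar = int(np.count_nonzero(np.triu(a, 1)))
        n = 12
        assert expected_density(s, zbar, n, 1, n) == pytest.approx(s.total / n)

    def test_value_scaling(self):
        rng = np.random.default_rng(10)
        a = random_symmetric(rng, 8).astype(float)
        s1, s2 = block_sums(a), block_sums(2 * a)
        zbar = int(np.count_nonzero(np.triu(a, 1)))
        assert expected_density(s2, zbar, 8, 2, 5) == pytest.approx(
            2 * expected_density(s1, zbar, 8, 2, 5)
        )

    def test_zbar_zero_undefined(self):
        s = block_sums(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            expected_density(s, 0, 4, 1, 4)


class TestFilterCores:
    def test_planted_dense_block_kept(self):
        a = np.zeros((20, 20), dtype=np.int64)
        a[np.ix_(range(5), range(5))] = 8
        a[10, 15] = a[15, 10] = 1
        np.fill_diagonal(a, 0)
        m = matrix_from(a)
        kept = identify_cores(m)
        assert any(c.p == 1 and c.q == 5 for c in kept)
        for c in kept:
            assert c.density > c.expected_density

    def test_uniform_matrix_keeps_nothing(self):
        a = np.full((10, 10), 2, dtype=np.int64)
        np.fill_diagonal(a, 0)
        m = matrix_from(a, k=3)
        assert identify_cores(m) == []

    def test_singletons_always_dropped(self):
        rng = np.random.default_rng(14)
        a = rng.integers(0, 3, size=(12, 12))
        a = np.triu(a, 1)
        a = a + a.T
        m = matrix_from(a)
        s = block_sums(m.values)
        kept = filter_cores(find_cores(m), s, m.zbar, m.n)
        assert all(c.size > 1 for c in kept)

    def test_empty_matrix_reports_no_cores(self, caplog):
        m = matrix_from(np.zeros((5, 5), dtype=np.int64))
        with caplog.at_level("WARNING"):
            kept = filter_cores(find_cores(m), block_sums(m.values), 0, 5)
        assert kept == []

    def test_kept_cores_disjoint_ordered(self):
        rng = np.random.default_rng(15)
        a = random_symmetric(rng, 30)
        m = matrix_from(a)
        kept = identify_cores(m)
        for c1, c2 in zip(kept, kept[1:]):
            assert c1.q < c2.p
        for c in kept:
            assert 1 <= c.p <= c.q <= 30


class TestCohesion:
    def triangle(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        return g

    def test_isolated_clique_infinite(self):
        assert cohesion(["a", "b", "c"], self.triangle()) == math.inf

    def test_half(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("a", "x"), ("b", "y")])
        assert cohesion(["a", "b"], g) == pytest.approx(0.5)

    def test_star_center_zero(self):
        import networkx as nx

        g = nx.star_graph(["hub", "l1", "l2", "l3"])
        assert cohesion(["hub"], g) == 0.0

    def test_no_incident_edges(self):
        assert cohesion(["z1", "z2"], self.triangle()) == 0.0


class TestParseNetwork:
    def test_dedup_and_self_loop(self, tmp_path, caplog):
        p = tmp_path / "net.tsv"
        p.write_text("a b\nb a\na a\n")
        with caplog.at_level("WARNING"):
            g = parse_network(p)
        assert g.number_of_edges() == 1
        assert "self-loop" in caplog.text

    def test_empty_file(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("# nothing\n")
        g = parse_network(p)
        assert g.number_of_edges() == 0
        assert cohesion(["a", "b"], g) == 0.0

    def test_triangle_file(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a b\nb c\nc a\n")
        assert parse_network(p).number_of_edges() == 3

    def test_malformed_line(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a b c\n")
        with pytest.raises(ValueError):
            parse_network(p)
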