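"""Louvain clustering, modularity, age binning, and the trivial partition.

Brute-force enumeration of all set partitions is the oracle for small
graphs; networkx provides the independent modularity cross-check.
"""

from itertools import permutations

import networkx as nx
import numpy as np
import pytest

from istg.clustering import (
    Partition,
    louvain_partition,
    modularity,
    partition_by_age,
    single_partition,
)
from istg.similarity import SimilarityGraph


def graph_from_weights(w):
    return SimilarityGraph([str(i) for i in range(w.shape[0])], w)


def set_partitions(n):
    """All set partitions of range(n) as label arrays (Bell(n) of them)."""
    if n == 1:
        yield [0]
        return
    for rest in set_partitions(n - 1):
        k = max(rest) + 1
        for lab in range(k + 1):
            yield rest + [lab]


def brute_force_max_modularity(g: SimilarityGraph, resolution=1.0):
    best_q, best_labels = -np.inf, None
    n = len(g.ids)
    for labels in set_partitions(n):
        p = Partition(g.ids, dict(zip(g.ids, labels)), "brute")
        q = modularity(g, p, resolution)
        if q > best_q:
            best_q, best_labels = q, list(labels)
    return best_q, best_labels


def two_cliques_graph():
    w = np.zeros((6, 6))
    for block in (range(3), range(3, 6)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    # tiny bridge so the similarity-graph positivity invariant holds
    return w


def labels_match(labels_a, labels_b):
    ka, kb = max(labels_a) + 1, max(labels_b) + 1
    if ka != kb:
        return False
    return any(
        all(pm[x] == y for x, y in zip(labels_a, labels_b))
        for pm in permutations(range(ka))
    )


class TestModularity:
    def test_single_community_is_zero(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 2.0, (5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = graph_from_weights(w)
        p = single_partition(g.ids)
        assert modularity(g, p, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_formula_collapse(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.1, 2.0, (4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = graph_from_weights(w)
        p = Partition(g.ids, {i: k for k, i in enumerate(g.ids)}, "singletons")
        k = w.sum(axis=1)
        expected = -np.sum((k / w.sum()) ** 2)
        assert modularity(g, p, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_two_clique_partition_is_half(self):
        w = two_cliques_graph()
        w[w == 0] = 1e-9
        np.fill_diagonal(w, 0.0)
        g = graph_from_weights(w)
        p = Partition(g.ids, {g.ids[i]: i // 3 for i in range(6)}, "clique")
        assert modularity(g, p, 1.0) == pytest.approx(0.5, abs=1e-6)

    def test_unlabeled_node_rejected(self):
        g = graph_from_weights(np.array([[0.0, 1.0], [1.0, 0.0]]))
        p = Partition(["0"], {"0": 0}, "partial")
        with pytest.raises(ValueError, match="label"):
            modularity(g, p, 1.0)

    @pytest.mark.parametrize("resolution", [0.5, 1.0, 2.0])
    def test_matches_networkx(self, resolution):
        rng = np.random.default_rng(2)
        w = rng.uniform(0.1, 1.0, (7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = graph_from_weights(w)
        labels = rng.integers(0, 3, 7)
        labels[0:3] = [0, 1, 2]  # contiguity
        p = Partition(g.ids, dict(zip(g.ids, labels)), "random")
        G = nx.from_numpy_array(w)
        comms = [
            {i for i in range(7) if labels[i] == c} for c in np.unique(labels)
        ]
        want = nx.community.modularity(G, comms, weight="weight",
                                       resolution=resolution)
        assert modularity(g, p, resolution) == pytest.approx(want, abs=1e-12)


class TestLouvain:
    def test_two_cliques_recovered(self):
        w = two_cliques_graph()
        w[w == 0] = 1e-6
        np.fill_diagonal(w, 0.0)
        g = graph_from_weights(w)
        p = louvain_partition(g, seed=0)
        want_q, want_labels = brute_force_max_modularity(g)
        assert p.modularity == pytest.approx(want_q, abs=1e-6)
        assert p.modularity == pytest.approx(0.5, abs=1e-3)
        assert labels_match([p.labels[i] for i in g.ids], want_labels)

    def test_complete_triangle_single_community(self):
        w = np.ones((3, 3)) - np.eye(3)
        g = graph_from_weights(w)
        p = louvain_partition(g, seed=0)
        want_q, _ = brute_force_max_modularity(g)
        assert p.n_groups == 1
        assert p.modularity == pytest.approx(0.0, abs=1e-12)
        assert want_q == pytest.approx(0.0, abs=1e-12)

    def test_planted_three_blocks_recovered_across_seeds(self):
        n_per, blocks = 10, 3
        n = n_per * blocks
        w = np.full((n, n), 0.1)
        for b in range(blocks):
            sl = slice(b * n_per, (b + 1) * n_per)
            w[sl, sl] = 1.0
        np.fill_diagonal(w, 0.0)
        g = graph_from_weights(w)
        truth = [i // n_per for i in range(n)]
        for seed in range(10):
            p = louvain_partition(g, seed=seed)
            assert labels_match([p.labels[i] for i in g.ids], truth), f"seed {seed}"

    def test_matches_brute_force_on_small_random_graphs(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = int(rng.integers(4, 8))
            w = rng.uniform(0.05, 1.0, (n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            g = graph_from_weights(w)
            best_q, _ = brute_force_max_modularity(g)
            p = louvain_partition(g, seed=0)
            assert p.modularity <= best_q + 1e-12

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(0.05, 1.0, (9, 9))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = graph_from_weights(w)
        p1 = louvain_partition(g, seed=11)
        p2 = louvain_partition(g, seed=11)
        assert p1.labels == p2.labels and p1.modularity == p2.modularity

    def test_local_maximum_no_single_move_improves(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.05, 1.0, (8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = graph_from_weights(w)
        p = louvain_partition(g, seed=0)
        labels = [p.labels[i] for i in g.ids]
        q0 = p.modularity
        for i in range(8):
            for c in range(max(labels) + 1):
                trial = list(labels)
                trial[i] = c
                uniq = sorted(set(trial))
                trial = [uniq.index(t) for t in trial]
                q = modularity(g, Partition(g.ids, dict(zip(g.ids, trial)), "t"), 1.0)
                assert q <= q0 + 1e-9

    def test_reported_modularity_consistent(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0.05, 1.0, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = graph_from_weights(w)
        p = louvain_partition(g, seed=0)
        assert p.modularity == pytest.approx(modularity(g, p, 1.0), abs=1e-12)


class TestAgePartition:
    def test_default_cutoffs(self):
        ids = list("abcdef")
        ages = dict(zip(ids, [1.2, 2.9, 3.0, 5.9, 6.0, 7.1]))
        p = partition_by_age(ids, ages)
        assert [p.labels[i] for i in ids] == [0, 0, 1, 1, 2, 2]

    def test_boundary_age_goes_up(self):
        p = partition_by_age(["a", "b"], {"a": 2.99, "b": 3.0})
        assert p.labels["a"] == 0 and p.labels["b"] == 1

    def test_all_in_one_bin_warns(self):
        with pytest.warns(UserWarning, match="empty age bin"):
            p = partition_by_age(["a", "b"], {"a": 1.0, "b": 2.0})
        assert p.n_groups == 1

    def test_missing_age_rejected(self):
        with pytest.raises(ValueError, match="missing age"):
            partition_by_age(["a", "b"], {"a": 1.0})


class TestSinglePartition:
    @pytest.mark.parametrize("n", [1, 5])
    def test_all_in_group_zero(self, n):
        p = single_partition([f"s{i}" for i in range(n)])
        assert p.n_groups == 1 and set(p.labels.values()) == {0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            single_partition([])


def test_partition_csv_round_trip(tmp_path):
    p = single_partition(["x", "y"])
    p.to_csv(tmp_path / "p.csv")
    back = Partition.from_csv(tmp_path / "p.csv")
    assert back.labels == p.labels
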