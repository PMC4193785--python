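"""Singleton-free partition enumeration and the exact subset DP."""

from itertools import combinations

import numpy as np
import pytest

from copulaclust import (
    Partition,
    WeightedBipartiteMatrix,
    best_partition,
    cluster_bipartite,
    enumerate_partitions,
)


def all_scores(labels, rng, scale=5.0):
    return {
        frozenset(c): float(rng.normal(scale=scale))
        for k in range(2, len(labels) + 1)
        for c in combinations(labels, k)
    }


def exhaustive_argmax(scores, labels):
    best_p, best_s = None, -np.inf
    for p in enumerate_partitions(labels):
        s = sum(scores[frozenset(b)] for b in p.blocks)
        if s > best_s:
            best_p, best_s = p, s
    return best_p, best_s


class TestEnumerate:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 1), (4, 4), (5, 11), (6, 41)])
    def test_counts(self, n, count):
        labels = [str(i) for i in range(1, n + 1)]
        parts = list(enumerate_partitions(labels))
        assert len(parts) == count
        assert len(set(parts)) == count  # each partition exactly once

    def test_four_actor_list(self):
        got = {p.as_sets() for p in enumerate_partitions(["1", "2", "3", "4"])}
        expected = {
            frozenset({frozenset({"1", "2"}), frozenset({"3", "4"})}),
            frozenset({frozenset({"1", "3"}), frozenset({"2", "4"})}),
            frozenset({frozenset({"1", "4"}), frozenset({"2", "3"})}),
            frozenset({frozenset({"1", "2", "3", "4"})}),
        }
        assert got == expected

    def test_too_few_actors(self):
        with pytest.raises(ValueError):
            list(enumerate_partitions(["only"]))

    def test_partition_rejects_singletons(self):
        with pytest.raises(ValueError):
            Partition((("a",), ("b", "c")))


class TestBestPartition:
    def test_worked_example(self):
        labels = ["1", "2", "3", "4"]
        scores = {frozenset(c): 0.0 for k in (2, 3, 4) for c in combinations(labels, k)}
        scores[frozenset({"1", "2"})] = 5.0
        scores[frozenset({"3", "4"})] = 5.0
        scores[frozenset(labels)] = 9.0
        part, score = best_partition(scores, labels)
        assert part == Partition((("1", "2"), ("3", "4")))
        assert score == pytest.approx(10.0)

    def test_degenerate_tie_prefers_single_block(self):
        labels = ["1", "2", "3", "4"]
        scores = {frozenset(c): 0.0 for k in (2, 3, 4) for c in combinations(labels, k)}
        part, score = best_partition(scores, labels)
        assert part == Partition((tuple(labels),))
        assert score == 0.0

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_dp_equals_exhaustive(self, n, rng):
        labels = [f"x{i}" for i in range(n)]
        for _ in range(20):
            scores = all_scores(labels, rng)
            part, score = best_partition(scores, labels)
            ex_part, ex_score = exhaustive_argmax(scores, labels)
            assert score == pytest.approx(ex_score, rel=1e-12)
            assert part == ex_part

    def test_returned_score_dominates_every_partition(self, rng):
        labels = [f"x{i}" for i in range(6)]
        scores = all_scores(labels, rng)
        _, score = best_partition(scores, labels)
        for p in enumerate_partitions(labels):
            assert score >= sum(scores[frozenset(b)] for b in p.blocks) - 1e-12

    def test_missing_score_raises(self):
        labels = ["1", "2", "3", "4"]
        scores = all_scores(labels, np.random.default_rng(0))
        del scores[frozenset({"1", "3"})]
        with pytest.raises(KeyError):
            best_partition(scores, labels)


class TestClusterBipartite:
    def test_recovers_planted_pairs(self, small_matrix):
        res = cluster_bipartite(small_matrix, "gumbel")
        assert res.partition == Partition((("a", "b"), ("c", "d")))
        assert res.global_loglik == pytest.approx(sum(f.max_loglik for f in res.fits))
        lls = [f.max_loglik for f in res.fits]
        assert lls == sorted(lls, reverse=True)

    def test_row_permutation_invariance(self, small_matrix, rng):
        res = cluster_bipartite(small_matrix, "clayton")
        perm = rng.permutation(small_matrix.n_actors)
        shuffled = WeightedBipartiteMatrix(
            tuple(small_matrix.actor_labels[i] for i in perm),
            small_matrix.feature_labels,
            small_matrix.values[perm],
        )
        res2 = cluster_bipartite(shuffled, "clayton")
        assert res2.partition == res.partition
        assert res2.global_loglik == pytest.approx(res.global_loglik, rel=1e-9)

    def test_exact_search_guard(self, small_matrix):
        with pytest.raises(ValueError, match="guard"):
            cluster_bipartite(small_matrix, "clayton", max_actors=3)
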