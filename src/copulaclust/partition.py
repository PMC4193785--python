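"""Exact optimisation over singleton-free partitions of the actor set.

The clustering objective is the *global log-likelihood*: the sum over a
partition's blocks of each block's maximised copula log-likelihood.  The
feasible set is every partition of the N actors whose blocks all have at
least two members.  Rather than listing all such partitions, the argmax
is found by dynamic programming over subset bitmasks (optimal
singleton-free cover of each mask), which provably returns the same
partition as exhaustive enumeration at ~3^N cost instead of the Bell-like
count — exact up to N around 16-18 on one core; a hard guard refuses
larger inputs.

Ties are broken deterministically: higher score, then fewer blocks, then
lexicographically smallest block list (by actor position in the input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np

from .copulas import CopulaFamily, get_family
from .likelihood import ClusterFit, SubsetFitter
from .margins import WeightedBipartiteMatrix, pseudo_observations

__all__ = [
    "Partition",
    "ClusteringResult",
    "enumerate_partitions",
    "best_partition",
    "cluster_bipartite",
    "MAX_EXACT_ACTORS",
]

#: beyond this the exact subset DP (and the 2^N - N - 1 subset fits) is
#: impractical on a single machine; callers must subsample first.
MAX_EXACT_ACTORS = 18


@dataclass(frozen=True)
class Partition:
    """A singleton-free set partition in canonical order.

    Blocks are tuples sorted internally and by first element; comparison
    as a set of sets is order-insensitive.
    """

    blocks: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        canon = tuple(sorted((tuple(sorted(map(str, b))) for b in self.blocks)))
        object.__setattr__(self, "blocks", canon)
        seen: set[str] = set()
        for b in canon:
            if len(b) < 2:
                raise ValueError(f"singleton or empty block {b!r} not allowed")
            if seen & set(b):
                raise ValueError("blocks are not disjoint")
            seen |= set(b)

    @property
    def actors(self) -> frozenset:
        return frozenset(a for b in self.blocks for a in b)

    def as_sets(self) -> frozenset:
        return frozenset(frozenset(b) for b in self.blocks)

    def __eq__(self, other) -> bool:
        if isinstance(other, Partition):
            return self.as_sets() == other.as_sets()
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.as_sets())

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class ClusteringResult:
    """Optimal partition with per-block fits, ordered by decreasing fit."""

    partition: Partition
    fits: tuple[ClusterFit, ...]
    global_loglik: float
    family: CopulaFamily

    def __post_init__(self) -> None:
        fits = tuple(sorted(self.fits, key=lambda f: -f.max_loglik))
        object.__setattr__(self, "fits", fits)
        total = sum(f.max_loglik for f in fits)
        if abs(total - self.global_loglik) > 1e-8 * max(1.0, abs(total)):
            raise ValueError("global_loglik must equal the sum of block fits")
        if Partition(tuple(f.members for f in fits)) != self.partition:
            raise ValueError("fits do not cover the partition blocks")


def enumerate_partitions(actor_labels: Sequence[str]) -> Iterator[Partition]:
    """Yield every partition of the actors into blocks of size >= 2.

    Counts follow the singleton-free partition numbers 1, 1, 4, 11, 41,
    ... for N = 2, 3, 4, 5, 6.
    """
    labels = [str(a) for a in actor_labels]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 actors")

    def rec(remaining: tuple[int, ...]) -> Iterator[tuple[tuple[int, ...], ...]]:
        if not remaining:
            yield ()
            return
        first, rest = remaining[0], remaining[1:]
        # choose the block containing the smallest remaining index
        for pick in range(1, 1 << len(rest)):
            mates = tuple(rest[i] for i in range(len(rest)) if pick >> i & 1)
            others = tuple(rest[i] for i in range(len(rest)) if not pick >> i & 1)
            if len(others) == 1:
                continue
            block = (first,) + mates
            for tail in rec(others):
                yield (block,) + tail

    for blocks in rec(tuple(range(n))):
        yield Partition(tuple(tuple(labels[i] for i in b) for b in blocks))


def _popcount(x: int) -> int:
    return bin(x).count("1")


def best_partition(
    scores: Mapping[frozenset, float],
    actor_labels: Sequence[str] | None = None,
) -> tuple[Partition, float]:
    """Exact argmax of the block-score sum over singleton-free partitions.

    ``scores`` maps every actor subset of size >= 2 (frozenset of labels)
    to its maximised block log-likelihood.  Dynamic programming over
    subset masks; deterministic tie-breaking (fewer blocks, then
    lexicographically smallest block list by actor position).
    """
    if actor_labels is None:
        labels = sorted({a for s in scores for a in s})
    else:
        labels = [str(a) for a in actor_labels]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 actors")
    if n > MAX_EXACT_ACTORS:
        raise ValueError(
            f"exact search is limited to {MAX_EXACT_ACTORS} actors (got {n}); "
            "subsample the actor set first"
        )

    full = (1 << n) - 1
    score_by_mask: dict[int, float] = {}
    for mask in range(full + 1):
        if _popcount(mask) >= 2:
            key = frozenset(labels[i] for i in range(n) if mask >> i & 1)
            try:
                score_by_mask[mask] = float(scores[key])
            except KeyError:
                raise KeyError(f"missing score for subset {tuple(sorted(key))}") from None
            if not np.isfinite(score_by_mask[mask]):
                raise ValueError(f"non-finite score for subset {tuple(sorted(key))}")

    # dp[mask] = (score, blocks-as-index-tuples) of the best singleton-free
    # partition of mask; None marks infeasible masks (size-1 remainders).
    dp: list[tuple[float, tuple[tuple[int, ...], ...]] | None] = [None] * (full + 1)
    dp[0] = (0.0, ())

    def better(a, b):
        """Pick the preferred of two candidates (score, blocks)."""
        if b is None:
            return a
        if a[0] != b[0]:
            return a if a[0] > b[0] else b
        if len(a[1]) != len(b[1]):
            return a if len(a[1]) < len(b[1]) else b
        return a if sorted(a[1]) <= sorted(b[1]) else b

    for mask in range(1, full + 1):
        if _popcount(mask) < 2:
            continue
        low = mask & -mask
        best = None
        # enumerate submasks of mask that contain its lowest set bit
        sub = mask
        while sub:
            if sub & low and _popcount(sub) >= 2:
                rest = mask ^ sub
                tail = dp[rest]
                if tail is not None:
                    block = tuple(i for i in range(n) if sub >> i & 1)
                    cand = (score_by_mask[sub] + tail[0], (block,) + tail[1])
                    best = better(cand, best)
            sub = (sub - 1) & mask
        dp[mask] = best

    score, blocks_idx = dp[full]
    partition = Partition(tuple(tuple(labels[i] for i in b) for b in blocks_idx))
    return partition, score


def cluster_bipartite(
    X: WeightedBipartiteMatrix,
    family: Union[str, CopulaFamily],
    *,
    max_actors: int = MAX_EXACT_ACTORS,
    fitter: SubsetFitter | None = None,
) -> ClusteringResult:
    """Full pipeline: margins -> every subset fit -> exact partition argmax.

    Fits all 2^N - N - 1 actor subsets of size >= 2 with the chosen
    Archimedean family, then runs the exact singleton-free partition
    optimisation.  Returns the optimal partition with blocks ordered by
    decreasing cluster log-likelihood.
    """
    family = get_family(family)
    n = X.n_actors
    if n > min(max_actors, MAX_EXACT_ACTORS):
        raise ValueError(
            f"{n} actors exceeds the exact-search guard "
            f"({min(max_actors, MAX_EXACT_ACTORS)}); subsample the actor set"
        )
    if fitter is None:
        fitter = SubsetFitter(pseudo_observations(X))

    labels = list(X.actor_labels)
    scores: dict[frozenset, float] = {}
    fits: dict[frozenset, ClusterFit] = {}
    for mask in range(1 << n):
        if _popcount(mask) < 2:
            continue
        members = tuple(labels[i] for i in range(n) if mask >> i & 1)
        fit = fitter.fit(members, family)
        key = frozenset(members)
        scores[key] = fit.max_loglik
        fits[key] = fit

    partition, score = best_partition(scores, labels)
    block_fits = tuple(fits[frozenset(b)] for b in partition.blocks)
    return ClusteringResult(
        partition=partition, fits=block_fits, global_loglik=score, family=family
    )
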