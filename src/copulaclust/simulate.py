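"""Planted-cluster simulation of weighted bipartite networks.

Each cluster of d actors is generated by drawing M points from a
d-dimensional Archimedean copula and pushing every coordinate through
the cluster's marginal quantile function (Sklar's converse), giving d
matrix rows with the prescribed within-cluster dependence and margins.
Stacking the clusters yields the N x M network; the planted partition is
the ground truth against which recovered partitions are scored.

The benchmark grid uses N = 10 actors in clusters of 3/4/3 with
dependence parameters theta = 4/3/4, one Archimedean family per
scenario, and Normal(0,1), Poisson(4) or mixed heavy-tailed margins;
item counts M in {20, 50, 100, 250}.  Discrete (Poisson) margins
intentionally produce ties, exercising the maximum-rank tie convention
of the margins module.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .copulas import CopulaFamily, CopulaModel, get_family
from .margins import WeightedBipartiteMatrix
from .partition import Partition, cluster_bipartite

__all__ = [
    "Margin",
    "ClusterSpec",
    "SimulationScenario",
    "benchmark_scenario",
    "generate_network",
    "run_experiment",
    "ExperimentResult",
]


@dataclass(frozen=True)
class Margin:
    """A named univariate margin with explicit parameters.

    Supported: normal(mu, sigma), poisson(lam), pareto(scale, shape),
    exponential(rate), lognormal(mu, sigma).  Parameters are named
    explicitly because shorthand like Pa(1, 2) is ambiguous about
    scale/shape order.
    """

    name: str
    params: tuple[float, ...]

    _BUILDERS = {
        "normal": lambda mu, sigma: stats.norm(loc=mu, scale=sigma),
        "poisson": lambda lam: stats.poisson(mu=lam),
        "pareto": lambda scale, shape: stats.pareto(b=shape, scale=scale),
        "exponential": lambda rate: stats.expon(scale=1.0 / rate),
        "lognormal": lambda mu, sigma: stats.lognorm(s=sigma, scale=float(np.exp(mu))),
    }

    def __post_init__(self) -> None:
        if self.name not in self._BUILDERS:
            raise ValueError(
                f"unknown margin {self.name!r}; choose from {sorted(self._BUILDERS)}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        self.frozen()  # validate parameters eagerly

    def frozen(self):
        return self._BUILDERS[self.name](*self.params)

    def ppf(self, q: np.ndarray) -> np.ndarray:
        return np.asarray(self.frozen().ppf(q), dtype=float)

    @classmethod
    def normal(cls, mu: float = 0.0, sigma: float = 1.0) -> "Margin":
        return cls("normal", (mu, sigma))

    @classmethod
    def poisson(cls, lam: float) -> "Margin":
        return cls("poisson", (lam,))

    @classmethod
    def pareto(cls, scale: float, shape: float) -> "Margin":
        return cls("pareto", (scale, shape))

    @classmethod
    def exponential(cls, rate: float) -> "Margin":
        return cls("exponential", (rate,))

    @classmethod
    def lognormal(cls, mu: float = 0.0, sigma: float = 1.0) -> "Margin":
        return cls("lognormal", (mu, sigma))


@dataclass(frozen=True)
class ClusterSpec:
    """One planted cluster: size, copula family, theta and margin."""

    d: int
    family: CopulaFamily
    theta: float
    margin: Margin

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", get_family(self.family))
        self.family.validate_theta(self.theta)
        if self.d < 2:
            raise ValueError("cluster size must be >= 2")


@dataclass(frozen=True)
class SimulationScenario:
    """A full planted-network recipe: clusters plus the item count M."""

    clusters: tuple[ClusterSpec, ...]
    M: int
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        if not self.clusters:
            raise ValueError("need at least one cluster")
        if self.M < 2:
            raise ValueError("M must be >= 2")

    @property
    def N(self) -> int:
        return sum(c.d for c in self.clusters)


# the 9-scenario benchmark: rows of three clusters sized 3/4/3 with
# theta 4/3/4; family cycles Gumbel/Clayton/Frank; margins switch from
# Normal(0,1) to Poisson(4) to a Pareto/Exponential/LogNormal mix.
_BENCH_FAMILIES = ("gumbel", "clayton", "frank")


def benchmark_scenario(s: int, M: int) -> SimulationScenario:
    """Scenario ``s`` in 1..9 of the standard benchmark grid, at item count M."""
    if not 1 <= s <= 9:
        raise ValueError("scenario number must be in 1..9")
    family = _BENCH_FAMILIES[(s - 1) % 3]
    if s <= 3:
        margins = [Margin.normal(0, 1)] * 3
    elif s <= 6:
        margins = [Margin.poisson(4)] * 3
    else:
        margins = [Margin.pareto(1, 2), Margin.exponential(0.5), Margin.lognormal(0, 1)]
    clusters = tuple(
        ClusterSpec(d=d, family=family, theta=theta, margin=m)
        for (d, theta), m in zip(((3, 4.0), (4, 3.0), (3, 4.0)), margins)
    )
    return SimulationScenario(clusters=clusters, M=M, label=f"S{s}")


def generate_network(
    scenario: SimulationScenario, seed
) -> tuple[WeightedBipartiteMatrix, Partition]:
    """Draw one planted network and its ground-truth partition.

    For each cluster, M samples from its d-dimensional copula are mapped
    coordinate-wise through the margin's quantile function and become d
    consecutive rows of X.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, blocks = [], []
    offset = 0
    for spec in scenario.clusters:
        model = CopulaModel(spec.family, spec.theta, spec.d)
        u = model.sample(scenario.M, rng)  # (M, d)
        rows.append(spec.margin.ppf(u).T)  # d rows of length M
        blocks.append(tuple(f"a{offset + i + 1:02d}" for i in range(spec.d)))
        offset += spec.d
    values = np.vstack(rows)
    actors = tuple(a for b in blocks for a in b)
    features = tuple(f"f{j + 1:03d}" for j in range(scenario.M))
    return WeightedBipartiteMatrix(actors, features, values), Partition(tuple(blocks))


@dataclass(frozen=True)
class ExperimentResult:
    """Success rate of exact cluster recovery over replicated networks."""

    scenario: SimulationScenario
    fit_family: CopulaFamily
    n_reps: int
    successes: int
    records: pd.DataFrame = field(repr=False)

    @property
    def rate(self) -> float:
        return self.successes / self.n_reps


def run_experiment(
    scenario: SimulationScenario,
    fit_family: Union[str, CopulaFamily],
    n_reps: int,
    seed: int,
) -> ExperimentResult:
    """Replicate generate -> cluster -> compare against the planted truth.

    Success in a replicate means the recovered partition equals the
    planted one as a set of sets.  Per-replicate seeds derive
    deterministically from the master seed, so the whole experiment is
    reproducible bit for bit.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fit_family = get_family(fit_family)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    recs = []
    successes = 0
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        X, truth = generate_network(scenario, rng)
        t0 = time.perf_counter()
        try:
            result = cluster_bipartite(X, fit_family)
            success = result.partition == truth
            error = ""
        except Exception as exc:  # a failed pipeline counts as a miss
            success, error = False, f"{type(exc).__name__}: {exc}"
        successes += int(success)
        recs.append(
            {
                "scenario": scenario.label or "custom",
                "M": scenario.M,
                "fit_family": fit_family.name,
                "rep": rep,
                "success": success,
                "runtime_s": time.perf_counter() - t0,
                "error": error,
            }
        )
    return ExperimentResult(
        scenario=scenario,
        fit_family=fit_family,
        n_reps=n_reps,
        successes=successes,
        records=pd.DataFrame.from_records(recs),
    )
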