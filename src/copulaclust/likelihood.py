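"""Maximum copula pseudo-likelihood for a candidate actor cluster.

For a subset of k actors the M columns of their pseudo-observations are
treated as i.i.d. draws from one k-variate Archimedean copula; the
cluster log-likelihood is

    l(theta) = sum_m log c_theta(u_{i1,m}, ..., u_{ik,m}),

maximised over theta by bounded derivative-free scalar search on a log
scale (log theta for Clayton/Frank, log(theta - 1) for Gumbel).  The
likelihood is unimodal in practice; comonotone rows legitimately push
theta to the upper cap, which is flagged, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.optimize import minimize_scalar

from .copulas import CopulaFamily, CopulaModel, get_family
from .margins import PseudoObservations

__all__ = ["ClusterFit", "FitError", "cluster_loglik", "fit_cluster", "SubsetFitter"]

# theta search intervals per family; lower ends sit just inside the
# admissible domain, upper ends at the numerically-comonotone caps.
_SEARCH_BOUNDS = {
    "gumbel": (1.0 + 1e-6, 50.0),
    "clayton": (1e-6, 50.0),
    "frank": (1e-6, 100.0),
}

_XATOL = 1e-6  # absolute tolerance on the transformed coordinate
_BOUND_TOL = 1e-3  # transformed-coordinate distance that counts as "at a bound"


class FitError(RuntimeError):
    """The log-likelihood is non-finite across the whole search interval."""


@dataclass(frozen=True)
class ClusterFit:
    """A fitted actor subset: members, theta-hat and the recorded maximum."""

    members: tuple[str, ...]
    family: CopulaFamily
    theta_hat: float
    max_loglik: float
    at_bound: bool

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")
        if not math.isfinite(self.max_loglik):
            raise ValueError("max_loglik must be finite")


def _to_theta(x: float, family: CopulaFamily) -> float:
    return 1.0 + math.exp(x) if family.name == "gumbel" else math.exp(x)


def _from_theta(theta: float, family: CopulaFamily) -> float:
    return math.log(theta - 1.0) if family.name == "gumbel" else math.log(theta)


def cluster_loglik(
    U: Union[PseudoObservations, np.ndarray],
    family: Union[str, CopulaFamily],
    theta: float,
) -> float:
    """Copula log-likelihood of a k-actor block at a given theta.

    ``U`` is the (k, M) block of pseudo-observations (or a
    PseudoObservations holding exactly the k actors).
    """
    values = U.values if isinstance(U, PseudoObservations) else np.asarray(U, float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a (k >= 2, M) block of pseudo-observations")
    model = CopulaModel(get_family(family), theta, values.shape[0])
    return float(np.sum(model.log_density(values.T)))


def fit_cluster(
    U: Union[PseudoObservations, np.ndarray],
    family: Union[str, CopulaFamily],
    members: tuple[str, ...] | None = None,
) -> ClusterFit:
    """Maximise the cluster log-likelihood over theta; deterministic.

    ``members`` labels the fit; if ``U`` is a PseudoObservations its own
    labels are used.
    """
    family = get_family(family)
    if isinstance(U, PseudoObservations):
        members = members or U.actor_labels
        values = U.values
    else:
        values = np.asarray(U, float)
        members = members or tuple(f"actor{i}" for i in range(values.shape[0]))
    if values.shape[0] < 2:
        raise ValueError("need at least 2 actors")
    points = values.T  # (M, k) evaluation points, fixed across theta
    model_dim = values.shape[0]

    lo, hi = _SEARCH_BOUNDS[family.name]
    xlo, xhi = _from_theta(lo, family), _from_theta(hi, family)

    def negll(x: float) -> float:
        model = CopulaModel(family, _to_theta(x, family), model_dim)
        try:
            return -float(np.sum(model.log_density(points)))
        except Exception:
            return np.inf

    res = minimize_scalar(
        negll, bounds=(xlo, xhi), method="bounded", options={"xatol": _XATOL}
    )
    if not np.isfinite(res.fun):
        raise FitError(
            f"{family.name} log-likelihood non-finite over the whole theta "
            f"range for subset {members}"
        )
    x_hat = float(res.x)
    theta_hat = _to_theta(x_hat, family)
    at_bound = (x_hat - xlo) < _BOUND_TOL or (xhi - x_hat) < _BOUND_TOL
    return ClusterFit(
        members=tuple(members),
        family=family,
        theta_hat=theta_hat,
        max_loglik=-float(res.fun),
        at_bound=at_bound,
    )


class SubsetFitter:
    """Fit-and-cache service over one matrix of pseudo-observations.

    The exact partition search needs every subset of size >= 2 exactly
    once, but callers may revisit subsets (e.g. with another family), so
    fits are memoised by member set and family.
    """

    def __init__(self, U: PseudoObservations):
        self.U = U
        self._cache: dict[tuple[frozenset, str], ClusterFit] = {}

    def fit(self, members, family: Union[str, CopulaFamily]) -> ClusterFit:
        family = get_family(family)
        members = tuple(sorted(members, key=self.U.actor_labels.index))
        key = (frozenset(members), family.name)
        hit = self._cache.get(key)
        if hit is None:
            hit = fit_cluster(self.U.subset(members), family, members)
            self._cache[key] = hit
        return hit

    @property
    def n_fits(self) -> int:
        return len(self._cache)
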