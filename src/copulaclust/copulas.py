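"""Archimedean copula kernels: CDF, log-density and exact sampling.

Implements the Gumbel, Clayton and Frank one-parameter families in any
dimension ``d >= 2``, restricted to positive dependence.  An Archimedean
copula is built from a generator :math:`\\psi`:

.. math::

    C(u_1, \\ldots, u_d) = \\psi\\bigl(\\psi^{-1}(u_1) + \\cdots +
    \\psi^{-1}(u_d)\\bigr),

and its density involves the d-th derivative of the generator,

.. math::

    c(\\mathbf u) = (-1)^d \\psi^{(d)}(t)\\Big|_{t=\\sum_i \\psi^{-1}(u_i)}
    \\; \\prod_i \\bigl|(\\psi^{-1})'(u_i)\\bigr|.

Naive symbolic differentiation of :math:`\\psi^{(d)}` is unstable beyond
dimension four or so; here each family uses a stable recursion evaluated
entirely in log space:

* Clayton — fully closed product form.
* Gumbel — polynomial coefficients of the d-th derivative of
  :math:`\\exp(-t^{1/\\theta})` via a two-term positive recursion.
* Frank — the d-th generator derivative equals a negative-order
  polylogarithm, expanded through Eulerian numbers.

Sampling uses the Marshall–Olkin frailty construction: draw a positive
frailty ``V`` (Gamma for Clayton, positive stable for Gumbel,
logarithmic-series for Frank) and set ``U_i = psi(E_i / V)`` with
independent unit exponentials ``E_i``.  This is exact, dimension-generic
and deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Union

import numpy as np
from scipy.special import logsumexp
from scipy.stats import logser

__all__ = [
    "CopulaFamily",
    "CopulaModel",
    "GUMBEL",
    "CLAYTON",
    "FRANK",
    "FAMILIES",
    "get_family",
    "copula_cdf",
    "copula_log_density",
    "sample_copula",
]

#: interior clip applied before density evaluation; rank-based
#: pseudo-observations never touch the boundary, but simulated or
#: user-supplied inputs can after float rounding.
_CLIP = 1e-10

#: dimensions beyond this overflow the generator-derivative recursions
#: (coefficients exceed double range); evaluation raises instead of
#: returning garbage.
_MAX_DIM = 64


class CopulaDomainError(ValueError):
    """Parameter or argument outside the admissible domain."""


@dataclass(frozen=True)
class CopulaFamily:
    """One Archimedean family with its admissible dependence range.

    ``theta_min``/``theta_max`` bound the admissible parameter;
    ``min_inclusive`` tells whether the lower end is attainable
    (Gumbel's theta = 1 is the independence copula and is legal, while
    Clayton and Frank reach independence only in the limit theta -> 0+).
    The upper caps mark where the family is numerically comonotone.
    """

    name: str
    theta_min: float
    theta_max: float
    min_inclusive: bool
    independence_limit: float

    def validate_theta(self, theta: float) -> float:
        theta = float(theta)
        if not np.isfinite(theta):
            raise CopulaDomainError(f"{self.name}: theta must be finite, got {theta}")
        low_ok = theta >= self.theta_min if self.min_inclusive else theta > self.theta_min
        if not (low_ok and theta <= self.theta_max):
            lo = "[" if self.min_inclusive else "("
            raise CopulaDomainError(
                f"{self.name}: theta={theta} outside admissible range "
                f"{lo}{self.theta_min}, {self.theta_max}]"
            )
        return theta


GUMBEL = CopulaFamily("gumbel", 1.0, 50.0, True, 1.0)
CLAYTON = CopulaFamily("clayton", 0.0, 50.0, False, 0.0)
FRANK = CopulaFamily("frank", 0.0, 100.0, False, 0.0)

FAMILIES = {f.name: f for f in (GUMBEL, CLAYTON, FRANK)}


def get_family(name: Union[str, CopulaFamily]) -> CopulaFamily:
    """Resolve a family by name (case-insensitive) or pass one through."""
    if isinstance(name, CopulaFamily):
        return name
    try:
        return FAMILIES[name.lower()]
    except KeyError:
        raise CopulaDomainError(
            f"unknown copula family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None


@dataclass(frozen=True)
class CopulaModel:
    """A fully specified copula: family, dependence parameter, dimension."""

    family: CopulaFamily
    theta: float
    dim: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", get_family(self.family))
        object.__setattr__(self, "theta", self.family.validate_theta(self.theta))
        if int(self.dim) != self.dim or self.dim < 2:
            raise CopulaDomainError(f"dimension must be an integer >= 2, got {self.dim}")
        if self.dim > _MAX_DIM:
            raise CopulaDomainError(
                f"dimension {self.dim} exceeds the numerically safe cap {_MAX_DIM}"
            )
        object.__setattr__(self, "dim", int(self.dim))

    def cdf(self, u: np.ndarray) -> Union[float, np.ndarray]:
        return copula_cdf(self, u)

    def log_density(self, u: np.ndarray) -> Union[float, np.ndarray]:
        return copula_log_density(self, u)

    def sample(self, n_samples: int, seed) -> np.ndarray:
        return sample_copula(self, n_samples, seed)


def _as_points(u: np.ndarray, d: int) -> tuple[np.ndarray, bool]:
    """Coerce input to an (n, d) array; remember if it was a single point."""
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    if single:
        u = u[None, :]
    if u.ndim != 2 or u.shape[1] != d:
        raise CopulaDomainError(
            f"expected a length-{d} vector or (n, {d}) array, got shape {u.shape}"
        )
    return u, single


# ---------------------------------------------------------------------------
# CDFs
# ---------------------------------------------------------------------------

def copula_cdf(model: CopulaModel, u: np.ndarray) -> Union[float, np.ndarray]:
    """Evaluate C(u) for one point (length-d vector) or a stack of points.

    Grounded (0 whenever any coordinate is 0) and reduces to the margin
    when all other coordinates are 1.
    """
    u, single = _as_points(u, model.dim)
    if np.any((u < 0) | (u > 1)):
        raise CopulaDomainError("copula arguments must lie in [0, 1]")
    theta, d = model.theta, model.dim

    with np.errstate(divide="ignore", over="ignore"):
        if model.family is GUMBEL:
            t = np.power(-np.log(u), theta).sum(axis=1)
            out = np.exp(-np.power(t, 1.0 / theta))
        elif model.family is CLAYTON:
            # sum(u^-theta) - (d-1) in log space to survive theta ~ 50
            lse = logsumexp(-theta * np.log(u), axis=1)
            with np.errstate(invalid="ignore"):
                log_s = lse + np.log1p(-(d - 1) * np.exp(-lse))
            out = np.exp(-log_s / theta)
            out = np.where(np.any(u == 0.0, axis=1), 0.0, out)
        else:  # FRANK
            log_p = np.log1p(-np.exp(-theta))
            with np.errstate(invalid="ignore"):
                log_q = np.log1p(-np.exp(-theta * u))
            log_x = log_q.sum(axis=1) - (d - 1) * log_p
            x = np.exp(log_x)
            out = -np.log1p(-x) / theta
            out = np.where(np.any(u == 0.0, axis=1), 0.0, out)

    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Log densities
# ---------------------------------------------------------------------------

def _gumbel_log_coefs(d: int, alpha: float) -> np.ndarray:
    """Log of the positive coefficients a_{d,k}, k = 1..d, in

        (-1)^d psi^(d)(t) = psi(t) * t^(-d) * sum_k a_{d,k} t^(k*alpha)

    for the Gumbel generator psi(t) = exp(-t^alpha).  Differentiating
    once more gives the two-term recursion

        a_{d+1,k} = alpha * a_{d,k-1} + (d - k*alpha) * a_{d,k},

    whose terms are all nonnegative for alpha <= 1, so the recursion is
    cancellation-free.
    """
    a = np.zeros(d + 1)
    a[1] = alpha
    for m in range(1, d):
        nxt = np.zeros(d + 1)
        for k in range(1, m + 2):
            nxt[k] = alpha * a[k - 1] + (m - k * alpha) * a[k]
        a = nxt
    with np.errstate(divide="ignore"):
        return np.log(a[1:])


@lru_cache(maxsize=None)
def _eulerian_log(n: int) -> np.ndarray:
    """Log Eulerian numbers <n, k>, k = 0..n-1 (n >= 1).

    They expand the negative-order polylogarithm
    Li_{-n}(x) = sum_k <n,k> x^(n-k) / (1-x)^(n+1) for 0 < x < 1.
    """
    e = np.zeros(1)  # <1, 0> = 1 in log space
    for m in range(2, n + 1):
        prev = np.concatenate([e, [-np.inf]])
        shifted = np.concatenate([[-np.inf], e])
        k = np.arange(m)
        e = np.logaddexp(np.log(k + 1.0) + prev, np.log(np.maximum(m - k, 1)) + shifted)
    return e


def copula_log_density(model: CopulaModel, u: np.ndarray) -> Union[float, np.ndarray]:
    """Log copula density, vectorised over points.

    Accepts a length-d vector or an (n, d) array of interior points and
    returns a float or length-n array.  Coordinates are clipped to
    ``[1e-10, 1 - 1e-10]``; exact 0/1 coordinates are rejected.
    """
    u, single = _as_points(u, model.dim)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise CopulaDomainError("log-density requires coordinates strictly inside (0, 1)")
    u = np.clip(u, _CLIP, 1.0 - _CLIP)
    theta, d = model.theta, model.dim

    if model.family is GUMBEL:
        out = _gumbel_log_density(u, theta, d)
    elif model.family is CLAYTON:
        out = _clayton_log_density(u, theta, d)
    else:
        out = _frank_log_density(u, theta, d)

    if not np.all(np.isfinite(out)):
        raise CopulaDomainError(
            f"{model.family.name} log-density overflowed at theta={theta}, d={d}"
        )
    return float(out[0]) if single else out


def _gumbel_log_density(u: np.ndarray, theta: float, d: int) -> np.ndarray:
    alpha = 1.0 / theta
    log_neg_log_u = np.log(-np.log(u))
    # t = sum_i (-log u_i)^theta, accumulated in log space
    log_t = logsumexp(theta * log_neg_log_u, axis=1)
    with np.errstate(divide="ignore"):
        log_a = _gumbel_log_coefs(d, alpha)
    k = np.arange(1, d + 1)
    log_poly = logsumexp(log_a[None, :] + k[None, :] * alpha * log_t[:, None], axis=1)
    log_g = -np.exp(alpha * log_t) - d * log_t + log_poly
    # |d/du psi^{-1}(u)| = theta * (-log u)^(theta-1) / u
    log_jac = d * np.log(theta) + (theta - 1.0) * log_neg_log_u.sum(axis=1) - np.log(u).sum(axis=1)
    return log_g + log_jac


def _clayton_log_density(u: np.ndarray, theta: float, d: int) -> np.ndarray:
    log_u = np.log(u)
    lse = logsumexp(-theta * log_u, axis=1)  # log sum u_i^-theta
    log_s = lse + np.log1p(-(d - 1) * np.exp(-lse))  # log(sum u^-theta - d + 1)
    j = np.arange(1, d)
    const = np.log1p(j * theta).sum()
    return const - (1.0 + theta) * log_u.sum(axis=1) - (d + 1.0 / theta) * log_s


def _frank_log_density(u: np.ndarray, theta: float, d: int) -> np.ndarray:
    n = d - 1
    # log1p(-exp(.)) keeps log(1 - e^-theta*u) accurate for large theta*u,
    # where forming 1 - e^-theta*u directly would round to 1 and push x
    # onto the Li pole at 1 for near-comonotone columns
    log_p = np.log1p(-np.exp(-theta))
    log_q = np.log1p(-np.exp(-theta * u))
    log_x = np.minimum(log_q.sum(axis=1) - n * log_p, -np.finfo(float).tiny)
    log_e = _eulerian_log(n)
    k = np.arange(n)
    log_li_num = logsumexp(log_e[None, :] + (n - k)[None, :] * log_x[:, None], axis=1)
    log_one_minus_x = np.log(-np.expm1(log_x))
    log_li = log_li_num - (n + 1) * log_one_minus_x  # log Li_{-n}(x)
    log_jac = d * np.log(theta) - theta * u.sum(axis=1) - log_q.sum(axis=1)
    return -np.log(theta) + log_li + log_jac


# ---------------------------------------------------------------------------
# Sampling (Marshall–Olkin frailty construction)
# ---------------------------------------------------------------------------

def _positive_stable(alpha: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """One-sided positive alpha-stable draws, Laplace transform exp(-s^alpha).

    Chambers–Mallows–Stuck construction with a uniform angle on (0, pi)
    and a unit exponential.
    """
    w = rng.uniform(0.0, np.pi, size=size)
    e = rng.standard_exponential(size=size)
    num = np.sin(alpha * w)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (num / np.sin(w) ** (1.0 / alpha)) * (
            np.sin((1.0 - alpha) * w) / e
        ) ** ((1.0 - alpha) / alpha)
    return s


def sample_copula(model: CopulaModel, n_samples: int, seed) -> np.ndarray:
    """Draw ``n_samples`` i.i.d. points from the copula.

    ``seed`` may be an int, a ``SeedSequence`` or a ``Generator``.
    Each column is marginally Uniform(0, 1); rows are independent.
    """
    if n_samples < 1:
        raise CopulaDomainError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta, d = model.theta, model.dim
    e = rng.standard_exponential(size=(n_samples, d))

    if model.family is GUMBEL:
        if theta == 1.0:  # frailty degenerates to the constant 1
            u = np.exp(-e)
        else:
            v = _positive_stable(1.0 / theta, n_samples, rng)
            u = np.exp(-np.power(e / v[:, None], 1.0 / theta))
    elif model.family is CLAYTON:
        v = rng.gamma(1.0 / theta, size=n_samples)
        u = np.power(1.0 + e / v[:, None], -1.0 / theta)
    else:  # FRANK
        p = -np.expm1(-theta)
        v = logser.rvs(p, size=n_samples, random_state=rng).astype(float)
        u = -np.log1p(-p * np.exp(-e / v[:, None])) / theta

    return np.clip(u, _CLIP, 1.0 - _CLIP)
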