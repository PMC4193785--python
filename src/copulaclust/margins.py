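"""Per-actor empirical margins and rank-based pseudo-observations.

Each actor's M feature weights are treated as i.i.d. draws from that
actor's own univariate distribution; its empirical CDF, rescaled by
M/(M+1) to stay off the boundary, maps the row into (0, 1).  These
pseudo-observations are the copula arguments for maximum
pseudo-likelihood.  Ties (signed or count data) receive the maximum
rank, so equal inputs map to equal outputs, consistent with a literal
empirical CDF.  A constant row carries no ordinal information and is a
hard error rather than something to jitter: fabricated noise would
fabricate dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DegenerateMarginError",
    "WeightedBipartiteMatrix",
    "PseudoObservations",
    "empirical_cdf_row",
    "pseudo_observations",
]


class DegenerateMarginError(ValueError):
    """A row is constant, so its empirical margin is degenerate."""


def _check_labels(labels: tuple[str, ...], what: str) -> None:
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate {what} labels: {dupes}")


@dataclass(frozen=True)
class WeightedBipartiteMatrix:
    """An N x M actor-by-feature weight matrix with labels.

    A zero weight means an absent edge and is an ordinary, informative
    value — which features an actor does *not* express is part of its
    position.
    """

    actor_labels: tuple[str, ...]
    feature_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "actor_labels", tuple(map(str, self.actor_labels)))
        object.__setattr__(self, "feature_labels", tuple(map(str, self.feature_labels)))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n, m = values.shape if values.ndim == 2 else (0, 0)
        if n < 2 or m < 2:
            raise ValueError(f"need at least a 2 x 2 matrix, got shape {values.shape}")
        if len(self.actor_labels) != n or len(self.feature_labels) != m:
            raise ValueError("label lengths do not match the value matrix shape")
        if not np.all(np.isfinite(values)):
            raise ValueError("all weights must be finite")
        _check_labels(self.actor_labels, "actor")
        _check_labels(self.feature_labels, "feature")

    @property
    def n_actors(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "WeightedBipartiteMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.actor_labels),
            columns=list(self.feature_labels),
        )

    def row(self, actor: str) -> np.ndarray:
        return self.values[self.actor_labels.index(actor)]


@dataclass(frozen=True)
class PseudoObservations:
    """Row-wise rank transforms of a weight matrix, strictly inside (0, 1)."""

    actor_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "actor_labels", tuple(map(str, self.actor_labels)))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or len(self.actor_labels) != values.shape[0]:
            raise ValueError("labels do not match the value matrix")
        if np.any(values <= 0.0) or np.any(values >= 1.0):
            raise ValueError("pseudo-observations must lie strictly in (0, 1)")
        _check_labels(self.actor_labels, "actor")

    @property
    def n_actors(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, actors) -> np.ndarray:
        """Rows for the given actor labels, in the given order."""
        idx = [self.actor_labels.index(a) for a in actors]
        return self.values[idx]


def empirical_cdf_row(row: np.ndarray) -> np.ndarray:
    """Rescaled empirical CDF of one row: maximum rank under ties / (M+1).

    Equivalent to (M/(M+1)) * ECDF(value); the rescaling keeps the row
    maximum at M/(M+1) < 1 so every Archimedean log-density stays finite.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise ValueError("row must be a vector of at least 2 values")
    if np.ptp(row) == 0.0:
        raise DegenerateMarginError("constant row: empirical margin is degenerate")
    return rankdata(row, method="max") / (row.size + 1.0)


def pseudo_observations(X: WeightedBipartiteMatrix) -> PseudoObservations:
    """Apply the rescaled empirical CDF to every actor row of X."""
    rows = []
    for label, row in zip(X.actor_labels, X.values):
        try:
            rows.append(empirical_cdf_row(row))
        except DegenerateMarginError:
            raise DegenerateMarginError(
                f"actor {label!r} has a constant feature row; its empirical "
                "margin carries no information"
            ) from None
    return PseudoObservations(X.actor_labels, np.vstack(rows))
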