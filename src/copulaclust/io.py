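"""Reading and writing matrices, results and the packaged voting fixture.

Matrices travel as labelled CSV/TSV (first column = actor labels, header
row = feature labels) or as a three-column weighted bipartite edge list
``actor,feature,weight`` where absent pairs mean weight zero.  Results
are written as JSON (machine-readable, round-trippable) with an optional
human-readable summary.
"""

from __future__ import annotations

import json
from importlib import metadata, resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .copulas import get_family
from .likelihood import ClusterFit
from .margins import WeightedBipartiteMatrix
from .partition import ClusteringResult, Partition

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_result",
    "read_result",
    "format_result",
    "supreme_court",
]


def _package_version() -> str:
    try:
        return metadata.version("copulaclust")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _detect_dialect(path: Path) -> str:
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "labeled-tsv"
    return "labeled-csv"


def read_matrix(path, dialect: str | None = None) -> WeightedBipartiteMatrix:
    """Read an actor-by-feature matrix from delimited text.

    ``dialect`` is one of ``labeled-csv``, ``labeled-tsv`` or
    ``bipartite-edge-list``; by default it is inferred from the file
    extension, with edge lists recognised by their three-column
    ``actor/feature/weight`` header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        head = pd.read_csv(path, sep=None, engine="python", nrows=1)
        if list(map(str.lower, map(str, head.columns))) == ["actor", "feature", "weight"]:
            dialect = "bipartite-edge-list"
        else:
            dialect = _detect_dialect(path)

    if dialect == "bipartite-edge-list":
        edges = pd.read_csv(path, sep=None, engine="python")
        if edges.shape[1] != 3:
            raise ValueError("edge list must have exactly 3 columns: actor, feature, weight")
        edges.columns = ["actor", "feature", "weight"]
        dup = edges.duplicated(subset=["actor", "feature"])
        if dup.any():
            pairs = edges.loc[dup, ["actor", "feature"]].to_records(index=False).tolist()
            raise ValueError(f"repeated (actor, feature) pairs: {pairs[:5]}")
        edges["weight"] = pd.to_numeric(edges["weight"])
        df = (
            edges.pivot(index="actor", columns="feature", values="weight")
            .sort_index(axis=0)
            .sort_index(axis=1)
            .fillna(0.0)  # absent pair = absent edge = weight 0
        )
    elif dialect in {"labeled-csv", "labeled-tsv"}:
        sep = "\t" if dialect == "labeled-tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("duplicate actor or feature labels")
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if df.empty:
        raise ValueError(f"empty matrix in {path}")
    return WeightedBipartiteMatrix.from_dataframe(df)


def write_matrix(X: WeightedBipartiteMatrix, path) -> None:
    """Write a labelled CSV/TSV (separator chosen by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = X.to_dataframe()
    df.index.name = "actor"
    df.to_csv(path, sep=sep)


def write_result(
    result: ClusteringResult, path, *, seed: int | None = None, summary: bool = True
) -> dict:
    """Write a clustering result as round-trippable JSON.

    The report lists blocks in decreasing cluster log-likelihood order
    with theta-hat and per-cluster log-likelihoods, plus the family,
    software version and optional seed.  A ``.txt`` summary is written
    alongside when ``summary`` is true.
    """
    payload = {
        "family": result.family.name,
        "global_loglik": result.global_loglik,
        "n_clusters": len(result.partition),
        "seed": seed,
        "version": _package_version(),
        "clusters": [
            {
                "members": list(f.members),
                "theta_hat": f.theta_hat,
                "loglik": f.max_loglik,
                "at_bound": f.at_bound,
            }
            for f in result.fits
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    if summary:
        path.with_suffix(path.suffix + ".txt").write_text(format_result(result))
    return payload


def read_result(path) -> ClusteringResult:
    """Reconstruct a ClusteringResult from a JSON report."""
    payload = json.loads(Path(path).read_text())
    family = get_family(payload["family"])
    fits = tuple(
        ClusterFit(
            members=tuple(c["members"]),
            family=family,
            theta_hat=float(c["theta_hat"]),
            max_loglik=float(c["loglik"]),
            at_bound=bool(c["at_bound"]),
        )
        for c in payload["clusters"]
    )
    partition = Partition(tuple(f.members for f in fits))
    return ClusteringResult(
        partition=partition,
        fits=fits,
        global_loglik=float(payload["global_loglik"]),
        family=family,
    )


def format_result(result: ClusteringResult) -> str:
    """Human-readable cluster summary, blocks in decreasing fit order."""
    lines = [
        f"copula family : {result.family.name}",
        f"clusters      : {len(result.partition)}",
        f"global loglik : {result.global_loglik:.4f}",
        "",
    ]
    for rank, fit in enumerate(result.fits, 1):
        bound = "  (theta at search bound)" if fit.at_bound else ""
        lines.append(
            f"cluster {rank}: {{{', '.join(fit.members)}}}  "
            f"theta={fit.theta_hat:.4f}  loglik={fit.max_loglik:.4f}{bound}"
        )
    return "\n".join(lines) + "\n"


def supreme_court() -> WeightedBipartiteMatrix:
    """The packaged 9-justice x 26-issue signed voting matrix.

    Votes are +1 (majority), -1 (minority) and a single 0 abstention;
    the abstention is treated as an ordinary third value of that row.
    """
    with resources.as_file(
        resources.files("copulaclust.data") / "supreme_court.csv"
    ) as p:
        return read_matrix(p, dialect="labeled-csv")
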