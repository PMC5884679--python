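"""Phenotype clustering of screened strains.

Each strain (or strain replicate) is summarized by ten measurements — O,
G, eta2(O), eta2(G) and eta2(P) at each of two pheromone doses.  The
matrix is log10-transformed and each row median-centered, strains are
compared with the Pearson-correlation distance (1 - r across the ten
measurements), and clusters are formed by unweighted average linkage
(UPGMA).  Log base does not affect Pearson distances after centering; base
10 is used for readability of the centered values.

Cluster signatures summarize each cluster per measurement as higher /
lower / near the strain medians, with an "any" state when the within-
cluster spread is too large to call.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .exceptions import DomainError, InsufficientDataError, ParameterError, SchemaError

__all__ = [
    "strain_phenotype_matrix",
    "preprocess_matrix",
    "cluster_strains",
    "cluster_signature",
]

PHENOTYPE_VARIABLES = ("O", "G", "eta2_O", "eta2_G", "eta2_P_plus_gamma")


def strain_phenotype_matrix(
    decomposition_rows: pd.DataFrame,
    doses: Sequence[float] = (0.6, 20.0),
    *,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Build the strains x 10 measurement matrix from a decomposition table.

    Columns are ``{variable}@{dose}nM`` for the five variables at each
    dose.  With ``per_replicate`` each strain replicate is a separate row
    (index ``strain//replicate``), mirroring screens that cluster replicate
    cultures individually; otherwise replicates are averaged per strain.
    """
    for col in ("strain", "dose_nM", *PHENOTYPE_VARIABLES):
        if col not in decomposition_rows.columns:
            raise SchemaError(f"missing required column '{col}'")
    df = decomposition_rows.copy()
    if per_replicate:
        df["__row"] = df["strain"].astype(str) + "//" + df["replicate"].astype(str)
    else:
        df["__row"] = df["strain"].astype(str)
    pieces = []
    for dose in doses:
        sub = df[np.isclose(df["dose_nM"], dose)]
        if sub.empty:
            raise InsufficientDataError(f"no rows at dose {dose} nM")
        wide = sub.groupby("__row")[list(PHENOTYPE_VARIABLES)].mean()
        wide.columns = [f"{v}@{dose:g}nM" for v in PHENOTYPE_VARIABLES]
        pieces.append(wide)
    mat = pd.concat(pieces, axis=1, join="inner")
    mat.index.name = "strain"
    return mat.sort_index()


def preprocess_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """log10-transform, then median-center each row."""
    values = matrix.to_numpy(dtype=float)
    bad = ~(values > 0) | ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DomainError(
            f"nonpositive entry for strain {matrix.index[i]!r}, "
            f"measurement {matrix.columns[j]!r}"
        )
    logged = np.log10(values)
    centered = logged - np.median(logged, axis=1, keepdims=True)
    return pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)


def cluster_strains(
    matrix: pd.DataFrame,
    *,
    n_clusters: int | None = None,
    cut_height: float | None = None,
) -> dict:
    """UPGMA clustering with Pearson-correlation distance between rows.

    ``matrix`` is the preprocessed (log10, median-centered) matrix.  Rows
    with zero variance (Pearson correlation undefined) are excluded with a
    warning and listed in the result.  Rows are sorted lexicographically by
    index first so merge order is deterministic.

    Returns a dict with ``linkage`` (scipy linkage matrix), ``labels``
    (flat labels as a Series, when a cut was requested), ``strains`` (row
    order used), and ``excluded``.
    """
    if len(matrix) < 2:
        raise InsufficientDataError("need at least 2 rows to cluster")
    mat = matrix.sort_index()
    values = mat.to_numpy(dtype=float)
    variances = values.var(axis=1)
    excluded = list(mat.index[variances == 0])
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} zero-variance row(s): {excluded}", stacklevel=2
        )
        mat = mat.loc[variances > 0]
        values = mat.to_numpy(dtype=float)
    if len(mat) < 2:
        raise InsufficientDataError("fewer than 2 rows with nonzero variance")

    dist = pdist(values, metric="correlation")
    z = linkage(dist, method="average")
    labels = None
    if n_clusters is not None:
        labels = pd.Series(
            fcluster(z, t=n_clusters, criterion="maxclust"), index=mat.index, name="cluster"
        )
    elif cut_height is not None:
        labels = pd.Series(
            fcluster(z, t=cut_height, criterion="distance"), index=mat.index, name="cluster"
        )
    return {
        "linkage": z,
        "labels": labels,
        "strains": list(mat.index),
        "excluded": excluded,
    }


def cluster_signature(
    cluster_rows: pd.DataFrame,
    eps: float = 0.1,
    dispersion_bound: float = 1.0,
) -> pd.Series:
    """Summarize a cluster's centered rows per measurement.

    For each measurement column: "any" when the within-cluster SD exceeds
    ``dispersion_bound``; otherwise "higher" / "lower" when the cluster
    median centered value is beyond ``+-eps``; else "median".
    """
    if len(cluster_rows) == 0:
        raise InsufficientDataError("empty cluster")
    if eps < 0 or dispersion_bound <= 0:
        raise ParameterError("eps must be >= 0 and dispersion_bound > 0")
    values = cluster_rows.to_numpy(dtype=float)
    med = np.median(values, axis=0)
    sd = values.std(axis=0, ddof=0)
    states = np.where(
        sd > dispersion_bound,
        "any",
        np.where(med > eps, "higher", np.where(med < -eps, "lower", "median")),
    )
    return pd.Series(states, index=cluster_rows.columns, name="signature")


def plot_heatmap(matrix: pd.DataFrame, path=None):  # pragma: no cover - visual aid
    """Red/black/green heat map of a centered phenotype matrix (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.2 * len(matrix))))
    vmax = np.abs(matrix.to_numpy()).max() or 1.0
    im = ax.imshow(matrix.to_numpy(), cmap="RdYlGn_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix)))
    ax.set_yticklabels(matrix.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="log10 centered value")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
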