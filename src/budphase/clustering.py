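"""Expression-profile clustering on Pearson-correlation distance.

Differentially expressed genes are grouped by the shape of their temporal
expression profile: the distance between two genes is 1 - r (Pearson
correlation across samples), profiles are standardized per gene to
z-scores, and an agglomerative tree cut at k groups yields the clusters.
Cluster centroids (mean member z-score per timepoint) are relabeled by
the chronology of their expression peak, and each gene's Pearson
correlation with its own centroid measures how well it represents the
cluster — the basis for marker selection.

Pearson distance is invariant to per-gene affine rescaling, so clustering
TPM profiles and clustering z-score profiles give identical partitions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import BudphaseError, ExpressionMatrix

_LINKAGES = ("complete", "average", "ward")


def _as_frame(expr) -> pd.DataFrame:
    if isinstance(expr, ExpressionMatrix):
        return expr.values
    return pd.DataFrame(expr)


def pearson_distance(expr) -> pd.DataFrame:
    """Gene x gene distance d(i,j) = 1 - Pearson r(i,j) across samples.

    d lies in [0, 2]; d(i,i) = 0; symmetric. Zero-variance gene rows have
    undefined correlation and are rejected (filter them out first).
    """
    values = _as_frame(expr)
    x = values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise BudphaseError("pearson_distance needs at least 2 samples")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = values.index[sd == 0].tolist()
        raise BudphaseError(f"zero-variance gene rows: {bad[:5]}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=values.index, columns=values.index)


def zscore(expr, ddof: int = 1) -> pd.DataFrame:
    """Per-gene standardization z = (x - mean) / sd across samples.

    Uses the sample standard deviation (``ddof=1``) by default; pass
    ``ddof=0`` for the population convention. Constant rows are rejected.
    """
    values = _as_frame(expr)
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=ddof)
    if (~np.isfinite(sd)).any() or (sd == 0).any():
        bad = values.index[~(np.isfinite(sd) & (sd > 0))].tolist()
        raise BudphaseError(f"constant gene rows cannot be z-scored: {bad[:5]}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=values.index, columns=values.columns)


class ProfileClusterer(BaseEstimator, ClusterMixin):
    """Agglomerative clustering of gene expression profiles.

    Parameters
    ----------
    n_clusters : int, default 10
        Number of groups to cut the tree into.
    linkage : {"complete", "average", "ward"}, default "complete"
        Agglomeration criterion. Ward operates on the Pearson-distance
        matrix directly (as scipy does for precomputed distances).
    metric : {"pearson", "precomputed"}, default "pearson"
        With "precomputed", ``fit`` expects a square distance matrix.

    Attributes
    ----------
    labels_ : pandas.Series
        Gene -> cluster label in 1..k (domain convention: cluster labels
        are 1-based, as in published cluster tables).
    linkage_matrix_ : ndarray
        The scipy linkage encoding of the agglomeration tree.
    """

    def __init__(self, n_clusters: int = 10, linkage: str = "complete",
                 metric: str = "pearson"):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.metric = metric

    def fit(self, X, y=None):
        if self.linkage not in _LINKAGES:
            raise BudphaseError(f"linkage must be one of {_LINKAGES}")
        if self.metric not in ("pearson", "precomputed"):
            raise BudphaseError("metric must be 'pearson' or 'precomputed'")
        X = _as_frame(X)
        if self.metric == "pearson":
            dist = pearson_distance(X)
        else:
            dist = X
            arr = dist.to_numpy(dtype=float)
            if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
                raise BudphaseError("precomputed distance must be square symmetric")
        n = dist.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise BudphaseError(
                f"n_clusters must be in [1, {n}], got {self.n_clusters}")
        condensed = squareform(dist.to_numpy(dtype=float), checks=False)
        self.linkage_matrix_ = hierarchy.linkage(condensed, method=self.linkage)
        flat = hierarchy.fcluster(self.linkage_matrix_, t=self.n_clusters,
                                  criterion="maxclust")
        self.labels_ = pd.Series(flat.astype(int), index=dist.index, name="cluster")
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def hierarchical_clusters(dist: pd.DataFrame, k: int = 10,
                          linkage: str = "complete") -> pd.Series:
    """Cut an agglomerative tree on a precomputed distance matrix into k groups."""
    clusterer = ProfileClusterer(n_clusters=k, linkage=linkage, metric="precomputed")
    return clusterer.fit(dist).labels_


def _timepoint_key(metadata: pd.DataFrame, by: str) -> pd.Series:
    meta = metadata.set_index("sample_id")
    if by == "date":
        return meta["date"]
    if by == "cultivar_date":
        return meta["cultivar"].astype(str) + "|" + meta["date"].astype(str)
    raise BudphaseError("by must be 'date' or 'cultivar_date'")


def timepoint_profiles(z: pd.DataFrame, metadata: pd.DataFrame,
                       by: str = "date") -> pd.DataFrame:
    """Average z-scores over replicate samples, genes x chronological timepoints.

    With ``by="date"`` replicate trees (and, when several cultivars are
    supplied, cultivars) sharing a date are averaged; ``by="cultivar_date"``
    keeps cultivars apart.
    """
    key = _timepoint_key(metadata, by).loc[z.columns]
    prof = z.T.groupby(key.to_numpy()).mean().T
    return prof[sorted(prof.columns)]


def cluster_centroids(z: pd.DataFrame, assignment: pd.Series,
                      metadata: pd.DataFrame, by: str = "date") -> pd.DataFrame:
    """Mean z-score per cluster and timepoint (clusters x timepoints)."""
    missing = assignment.index.difference(z.index)
    if len(missing):
        raise BudphaseError(f"clustered genes absent from z matrix: {missing.tolist()[:5]}")
    profiles = timepoint_profiles(z.loc[assignment.index], metadata, by=by)
    counts = assignment.value_counts()
    if (counts == 0).any():
        raise BudphaseError("cluster with zero members")
    cent = profiles.groupby(assignment).mean()
    cent.index.name = "cluster"
    return cent


def order_clusters_by_peak(centroids: pd.DataFrame,
                           assignment: pd.Series | None = None) -> dict:
    """Relabel clusters 1..k by the chronology of their expression peak.

    Clusters are sorted by the (chronologically ordered) timepoint index
    of their centroid maximum; ties are broken by larger cluster first
    (needs ``assignment`` for sizes; without it, ties fall back to the
    original label order).

    Returns a mapping old label -> new label.
    """
    peaks = centroids.to_numpy(dtype=float).argmax(axis=1)
    labels = list(centroids.index)
    if assignment is not None:
        sizes = assignment.value_counts()
        keys = [(peaks[i], -int(sizes.get(lab, 0)), i) for i, lab in enumerate(labels)]
    else:
        keys = [(peaks[i], 0, i) for i, lab in enumerate(labels)]
    order = sorted(range(len(labels)), key=lambda i: keys[i])
    return {labels[i]: new + 1 for new, i in enumerate(order)}


def relabel_clusters(assignment: pd.Series, mapping: dict) -> pd.Series:
    return assignment.map(mapping).rename(assignment.name)


def centroid_correlations(z: pd.DataFrame, centroids: pd.DataFrame,
                          assignment: pd.Series, metadata: pd.DataFrame,
                          by: str = "date") -> pd.Series:
    """Pearson r between each gene's timepoint profile and its own centroid.

    Computed on the same replicate-averaged timepoint axis used for the
    centroids, so a gene tracking its cluster mean exactly scores r = 1.
    """
    profiles = timepoint_profiles(z.loc[assignment.index], metadata, by=by)
    cent = centroids[profiles.columns]
    cent_sd = cent.to_numpy(dtype=float).std(axis=1)
    if (cent_sd == 0).any():
        bad = cent.index[cent_sd == 0].tolist()
        raise BudphaseError(f"constant centroids: {bad}")
    out = {}
    g = profiles.to_numpy(dtype=float)
    gc = g - g.mean(axis=1, keepdims=True)
    gn = np.linalg.norm(gc, axis=1)
    c = cent.to_numpy(dtype=float)
    cc = c - c.mean(axis=1, keepdims=True)
    cn = np.linalg.norm(cc, axis=1)
    cent_pos = {lab: i for i, lab in enumerate(cent.index)}
    for i, gene in enumerate(profiles.index):
        j = cent_pos[assignment.loc[gene]]
        if gn[i] == 0:
            raise BudphaseError(f"constant gene profile: {gene}")
        out[gene] = float(gc[i] @ cc[j] / (gn[i] * cn[j]))
    return pd.Series(out, name="centroid_r")


def write_assignment(assignment: pd.Series, path) -> None:
    assignment.rename("cluster").rename_axis("gene_id").reset_index() \
        .to_csv(path, sep="\t", index=False)


def read_assignment(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene_id")["cluster"].astype(int)
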