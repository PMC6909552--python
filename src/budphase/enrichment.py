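"""Over-representation tests for gene clusters.

Three annotation kinds share the same machinery: transcription-factor
target sets, promoter motif sets, and GO terms. For a cluster of n genes
drawn from a universe of N genes, K of which carry an annotation, the
over-representation p-value of observing k annotated genes in the cluster
is the hypergeometric upper tail P(X >= k) — identical to a one-sided
Fisher exact test on the 2x2 table. Per-cluster families of tests are
corrected with Benjamini-Hochberg.

The universe defaults to the tested gene set itself (typically the DEGs),
so enrichment is measured against the differentially expressed background
rather than the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BudphaseError

ANNOTATION_KINDS = ("tf_target", "motif", "go_term")


@dataclass
class AnnotationTable:
    """Gene -> set membership over a stated gene universe.

    ``records`` holds unique (gene_id, set_id) pairs; every annotated gene
    must belong to ``universe``.
    """

    kind: str
    records: pd.DataFrame  # columns: gene_id, set_id
    universe: frozenset

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise BudphaseError(f"kind must be one of {ANNOTATION_KINDS}, got {self.kind!r}")
        rec = self.records[["gene_id", "set_id"]].drop_duplicates()
        if (rec["set_id"].astype(str) == "").any():
            raise BudphaseError("empty set ids in annotation")
        self.universe = frozenset(self.universe)
        outside = set(rec["gene_id"]) - self.universe
        if outside:
            raise BudphaseError(
                f"annotated genes outside the universe: {sorted(outside)[:5]}")
        self.records = rec.reset_index(drop=True)

    def sets(self) -> dict[str, frozenset]:
        """Mapping set_id -> annotated genes."""
        return {sid: frozenset(g["gene_id"])
                for sid, g in self.records.groupby("set_id", sort=True)}

    def restrict(self, universe) -> "AnnotationTable":
        """Restrict the table to a sub-universe (e.g. the DEG set)."""
        universe = frozenset(universe)
        rec = self.records[self.records["gene_id"].isin(universe)]
        return AnnotationTable(self.kind, rec.reset_index(drop=True), universe)

    @classmethod
    def from_tsv(cls, path, kind: str, universe=None) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t")
        df.columns = ["gene_id", "set_id", *df.columns[2:]]
        if universe is None:
            universe = set(df["gene_id"])
        return cls(kind, df[["gene_id", "set_id"]], frozenset(universe))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise BudphaseError(f"invalid hypergeometric margins N={N}, K={K}, n={n}")
    if not (0 <= k <= min(n, K)):
        raise BudphaseError(f"invalid count k={k} for margins N={N}, K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise BudphaseError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q
    return out


def hypergeom_overrep(cluster_genes,
                      annotation: AnnotationTable,
                      universe=None,
                      cluster_label=None) -> pd.DataFrame:
    """Hypergeometric over-representation of every annotation set in one cluster.

    Returns one row per set with the 2x2 margins (k, n, K, N) and the raw
    upper-tail p-value. BH adjustment is applied by
    :func:`enrich_clusters` over the family of tests for the cluster.
    """
    universe = frozenset(universe) if universe is not None else annotation.universe
    if not universe:
        raise BudphaseError("empty universe")
    cluster = frozenset(cluster_genes)
    if not cluster:
        raise BudphaseError("empty cluster")
    if not cluster <= universe:
        raise BudphaseError("cluster genes must be a subset of the universe")
    table = annotation.restrict(universe)
    N, n = len(universe), len(cluster)
    rows = []
    for set_id, genes in table.sets().items():
        K = len(genes)
        k = len(genes & cluster)
        rows.append({
            "cluster": cluster_label, "set_id": set_id,
            "k": k, "n": n, "K": K, "N": N,
            "p_value": hypergeom_pvalue(k, N, K, n),
        })
    return pd.DataFrame(rows,
                        columns=["cluster", "set_id", "k", "n", "K", "N", "p_value"])


def enrich_clusters(assignment: pd.Series,
                    annotation: AnnotationTable,
                    universe=None,
                    family: str = "per_cluster") -> pd.DataFrame:
    """Test every (cluster, set) pair and BH-adjust.

    ``assignment`` maps gene_id -> cluster label. By default each cluster
    forms its own BH family (one correction per cluster x annotation
    kind), matching per-cluster reporting; ``family="global"`` corrects
    over all clusters jointly.
    """
    if family not in ("per_cluster", "global"):
        raise BudphaseError("family must be 'per_cluster' or 'global'")
    universe = frozenset(universe) if universe is not None else frozenset(assignment.index)
    frames = []
    for label in sorted(assignment.unique()):
        genes = assignment.index[assignment == label]
        res = hypergeom_overrep(genes, annotation, universe, cluster_label=label)
        if family == "per_cluster" and len(res):
            res["p_adjusted"] = bh_adjust(res["p_value"].to_numpy())
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    if family == "global" and len(out):
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


def go_fisher(cluster_genes,
              go_annotation: AnnotationTable,
              universe=None,
              p_cut: float = 0.005,
              top_n: int = 10,
              cluster_label=None) -> pd.DataFrame:
    """Classic one-sided Fisher GO enrichment for one cluster.

    The one-sided Fisher exact p on the 2x2 in-cluster/annotated table
    equals the hypergeometric upper tail, so this shares
    :func:`hypergeom_overrep` and then filters at raw p < ``p_cut`` and
    keeps the ``top_n`` terms with the lowest p (ties broken by set id).
    GO annotations are used flat, without ontology-graph propagation.
    """
    res = hypergeom_overrep(cluster_genes, go_annotation, universe,
                            cluster_label=cluster_label)
    res = res[res["p_value"] < p_cut]
    res = res.sort_values(["p_value", "set_id"], kind="stable")
    return res.head(top_n).reset_index(drop=True)


def write_enrichment(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
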