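"""Marker-panel selection: one representative gene per chosen cluster.

A stage-diagnostic panel needs genes that (i) track their cluster's mean
profile as closely as possible (highest centroid correlation), (ii) are
expressed highly enough to assay reliably, and (iii) do not belong to
large gene families (to avoid cross-amplification in qPCR). Clusters that
are very small or redundant with another cluster are typically left out;
the chosen-cluster set is a parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .containers import BudphaseError, ExpressionMatrix

DEFAULT_CLUSTERS = (1, 4, 5, 7, 8, 9, 10)


@dataclass
class MarkerPanel:
    """Selected marker genes, one per chosen cluster.

    ``entries`` has columns ``cluster gene_id r`` sorted by cluster label;
    ``criteria`` snapshots the selection thresholds.
    """

    entries: pd.DataFrame
    criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = self.entries[["cluster", "gene_id", "r"]] \
            .sort_values("cluster").reset_index(drop=True)
        if self.entries["cluster"].duplicated().any():
            raise BudphaseError("marker panel must have one gene per cluster")

    @property
    def gene_ids(self) -> list:
        return self.entries["gene_id"].tolist()

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {"entries": self.entries.to_dict(orient="records"),
                   "criteria": self.criteria}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(pd.DataFrame(payload["entries"]), payload.get("criteria", {}))


def read_family_table(path) -> pd.DataFrame:
    """TSV ``gene_id<TAB>family_id<TAB>family_size``."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "family_id", "family_size"}
    missing = required - set(df.columns)
    if missing:
        raise BudphaseError(f"family table missing columns: {sorted(missing)}")
    return df


def select_markers(corrs: pd.Series,
                   assignment: pd.Series,
                   tpm: ExpressionMatrix | pd.DataFrame,
                   family_table: pd.DataFrame | None = None,
                   clusters=DEFAULT_CLUSTERS,
                   min_mean_tpm: float = 10.0,
                   max_family_size: int = 5,
                   exclude=()) -> MarkerPanel:
    """Pick, per requested cluster, the eligible gene best correlated with
    its centroid.

    Eligibility: mean TPM >= ``min_mean_tpm``, family size <=
    ``max_family_size`` (genes absent from ``family_table`` count as
    singletons), and not in the user ``exclude`` list (e.g. genes for
    which no specific primers can be designed). Ties on r are broken by
    higher mean TPM, then lexicographic gene id, so the panel does not
    depend on input gene order.
    """
    values = tpm.values if isinstance(tpm, ExpressionMatrix) else pd.DataFrame(tpm)
    mean_tpm = values.mean(axis=1)
    family_size = pd.Series(1, index=assignment.index, dtype=int)
    if family_table is not None:
        fam = family_table.set_index("gene_id")["family_size"]
        family_size.update(fam)
    exclude = set(exclude)

    rows = []
    for cluster in sorted(set(clusters)):
        members = assignment.index[assignment == cluster]
        if len(members) == 0:
            raise BudphaseError(f"cluster {cluster} has no genes")
        candidates = pd.DataFrame({
            "gene_id": members,
            "r": corrs.reindex(members).to_numpy(),
            "mean_tpm": mean_tpm.reindex(members).to_numpy(),
            "family_size": family_size.reindex(members).fillna(1).to_numpy(),
        })
        if candidates["r"].isna().any():
            missing = candidates.loc[candidates["r"].isna(), "gene_id"].tolist()
            raise BudphaseError(f"missing centroid correlation for: {missing[:5]}")
        eligible = candidates[
            (candidates["mean_tpm"] >= min_mean_tpm)
            & (candidates["family_size"] <= max_family_size)
            & ~candidates["gene_id"].isin(exclude)
        ]
        if eligible.empty:
            n_expr = int((candidates["mean_tpm"] < min_mean_tpm).sum())
            n_fam = int((candidates["family_size"] > max_family_size).sum())
            n_exc = int(candidates["gene_id"].isin(exclude).sum())
            raise BudphaseError(
                f"cluster {cluster}: no eligible gene "
                f"(below min_mean_tpm: {n_expr}, family too large: {n_fam}, "
                f"excluded: {n_exc})")
        best = eligible.sort_values(
            ["r", "mean_tpm", "gene_id"], ascending=[False, False, True],
            kind="stable").iloc[0]
        rows.append({"cluster": cluster, "gene_id": best["gene_id"],
                     "r": float(best["r"])})

    criteria = {"clusters": sorted(set(clusters)),
                "min_mean_tpm": min_mean_tpm,
                "max_family_size": max_family_size,
                "n_excluded": len(exclude)}
    return MarkerPanel(pd.DataFrame(rows), criteria)
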