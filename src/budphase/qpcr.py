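"""RT-qPCR quantification by the relative standard-curve method.

A dilution series of pooled cDNA gives, per gene, an ordinary
least-squares fit of Cq on log10(quantity). Sample quantities are read
off the curve (quantity = 10^((Cq - intercept)/slope)) and normalized per
sample by the average quantity of constitutively expressed reference
genes, yielding relative expression values comparable across samples.

Amplification efficiency follows from the slope: a perfect doubling per
cycle gives slope -1/log10(2) = -3.32193 and efficiency 1.0 (100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BudphaseError


@dataclass
class StandardCurve:
    """Per-gene dilution-series calibration: Cq = intercept + slope*log10(Q)."""

    gene_id: str
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise BudphaseError(
                f"{self.gene_id}: standard-curve slope must be negative "
                f"(got {self.slope:.4g}); invalid assay")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency 10^(-1/slope) - 1 (1.0 == 100%)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(dilution_quantities, cq_values,
                       gene_id: str = "") -> StandardCurve:
    """OLS of Cq on log10(quantity) over a dilution series (>= 3 dilutions)."""
    q = np.asarray(dilution_quantities, dtype=float)
    cq = np.asarray(cq_values, dtype=float)
    if q.shape != cq.shape or q.ndim != 1:
        raise BudphaseError("dilution quantities and Cq values must align 1-D")
    if (q <= 0).any():
        raise BudphaseError("dilution quantities must be positive")
    if len(np.unique(q)) < 3:
        raise BudphaseError("need >= 3 distinct dilution points")
    if not np.isfinite(cq).all():
        raise BudphaseError("non-finite Cq in dilution series")
    res = stats.linregress(np.log10(q), cq)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0
    return StandardCurve(gene_id=gene_id, slope=float(res.slope),
                         intercept=float(res.intercept), r_squared=r2)


def quantify(curve: StandardCurve, cq) -> np.ndarray | float:
    """Invert the standard curve: quantity = 10^((Cq - intercept)/slope)."""
    cq_arr = np.asarray(cq, dtype=float)
    if not np.isfinite(cq_arr).all():
        raise BudphaseError(f"{curve.gene_id}: non-finite Cq value")
    q = 10.0 ** ((cq_arr - curve.intercept) / curve.slope)
    return float(q) if np.isscalar(cq) or cq_arr.ndim == 0 else q


def fit_standard_curves(standards: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one curve per gene from a long table
    ``gene_id, dilution_quantity, cq``."""
    required = {"gene_id", "dilution_quantity", "cq"}
    missing = required - set(standards.columns)
    if missing:
        raise BudphaseError(f"standards table missing columns: {sorted(missing)}")
    return {gene: fit_standard_curve(grp["dilution_quantity"], grp["cq"], gene_id=gene)
            for gene, grp in standards.groupby("gene_id", sort=True)}


def quantify_samples(cq_table: pd.DataFrame,
                     curves: dict[str, StandardCurve]) -> pd.DataFrame:
    """Quantities per (sample, gene) from a long Cq table.

    Technical replicate Cq values (duplicate sample/gene rows) are
    averaged before quantification; biological replicates are distinct
    samples and stay separate.
    """
    required = {"sample_id", "gene_id", "cq"}
    missing = required - set(cq_table.columns)
    if missing:
        raise BudphaseError(f"Cq table missing columns: {sorted(missing)}")
    mean_cq = cq_table.groupby(["sample_id", "gene_id"], sort=True)["cq"].mean()
    rows = []
    for (sample, gene), cq in mean_cq.items():
        if gene not in curves:
            raise BudphaseError(f"no standard curve for gene {gene!r}")
        rows.append({"sample_id": sample, "gene_id": gene,
                     "quantity": quantify(curves[gene], float(cq))})
    return pd.DataFrame(rows)


def normalize_by_reference(quantities: pd.DataFrame,
                           reference_gene_ids,
                           mean: str = "arithmetic") -> pd.DataFrame:
    """Divide each quantity by the per-sample average reference-gene quantity.

    Returns the long table with a ``normalized_value`` column (reference
    genes themselves are dropped from the output). The arithmetic mean is
    the default; ``mean="geometric"`` is available.
    """
    reference_gene_ids = list(reference_gene_ids)
    if not reference_gene_ids:
        raise BudphaseError("need at least one reference gene")
    if mean not in ("arithmetic", "geometric"):
        raise BudphaseError("mean must be 'arithmetic' or 'geometric'")
    if (quantities["quantity"] <= 0).any():
        raise BudphaseError("quantities must be positive")
    wide = quantities.pivot(index="gene_id", columns="sample_id", values="quantity")
    missing = set(reference_gene_ids) - set(wide.index)
    if missing:
        raise BudphaseError(f"reference genes not quantified: {sorted(missing)}")
    refs = wide.loc[reference_gene_ids]
    if refs.isna().any().any():
        bad = refs.columns[refs.isna().any(axis=0)].tolist()
        raise BudphaseError(f"samples missing reference quantities: {bad[:5]}")
    if mean == "arithmetic":
        ref_avg = refs.mean(axis=0)
    else:
        ref_avg = np.exp(np.log(refs).mean(axis=0))
    out = quantities[~quantities["gene_id"].isin(reference_gene_ids)].copy()
    if out["sample_id"].map(ref_avg).isna().any():
        raise BudphaseError("sample without reference-gene quantities")
    out["normalized_value"] = out["quantity"] / out["sample_id"].map(ref_avg)
    return out.reset_index(drop=True)


def relative_expression_matrix(normalized: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long normalized table to genes x samples."""
    return normalized.pivot(index="gene_id", columns="sample_id",
                            values="normalized_value")
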