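"""TPM computation, expression filtering, and a differential-expression caller.

The preprocessing contract mirrors a standard bulk RNA-seq workflow for
dormancy time courses: raw counts are converted to TPM, genes are filtered
by three sequential rules (low mean count, mostly-zero, low coefficient of
variation), and differential expression between dormant and non-dormant
samples is called.

The differential test shipped here, :func:`call_degs`, is a deliberately
simple two-group Welch test on log2(TPM+1) with Benjamini-Hochberg
correction, exposed behind a pluggable interface so a DEG list produced by
a dedicated count-model package (e.g. DESeq2 run separately) can be
supplied as a file instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import STAGES, BudphaseError, ExpressionMatrix, TPM_SCALE
from .enrichment import bh_adjust

#: Default dormant-side grouping for the DE contrast. The split of samples
#: into "dormant" and "non dormant" is a parameter, not an assertion.
DEFAULT_DORMANT_STAGES = frozenset({"endodormancy", "dormancy_release"})


@dataclass
class FilterReport:
    """Outcome of the three sequential gene filters."""

    n_input: int
    n_low_expression_removed: int
    n_mostly_zero_removed: int
    n_low_cv_removed: int
    surviving_gene_ids: pd.Index

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_gene_ids)

    def __post_init__(self) -> None:
        removed = (self.n_low_expression_removed + self.n_mostly_zero_removed
                   + self.n_low_cv_removed)
        if removed + self.n_surviving != self.n_input:
            raise BudphaseError("filter counts do not add up to n_input")


def compute_tpm(counts: ExpressionMatrix,
                gene_lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Convert raw read counts to transcripts per million.

    TPM_ij = (c_ij / L_i) / sum_g (c_gj / L_g) * 1e6, so every sample
    column sums to 1e6 and length bias is removed within samples.
    """
    if counts.unit != "count":
        raise BudphaseError(f"compute_tpm expects counts, got unit={counts.unit!r}")
    lengths = gene_lengths if gene_lengths is not None else counts.gene_lengths
    if lengths is None:
        raise BudphaseError("gene lengths are required to compute TPM")
    lengths = pd.Series(lengths)
    missing = counts.gene_ids.difference(lengths.index)
    if len(missing):
        raise BudphaseError(f"missing gene length for: {missing.tolist()[:5]}")
    lengths = lengths.loc[counts.gene_ids].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise BudphaseError(f"gene lengths must be positive: {bad[:5]}")

    rate = counts.values.to_numpy(dtype=float) / lengths.to_numpy()[:, None]
    denom = rate.sum(axis=0)
    zero_cols = counts.sample_ids[denom == 0].tolist()
    if zero_cols:
        raise BudphaseError(f"samples with zero total counts: {zero_cols[:5]}")
    tpm = rate / denom[None, :] * TPM_SCALE
    values = pd.DataFrame(tpm, index=counts.gene_ids, columns=counts.sample_ids)
    return ExpressionMatrix(values, unit="TPM",
                            gene_lengths=lengths.astype(int))


def filter_genes(counts: ExpressionMatrix,
                 tpm: ExpressionMatrix | None = None,
                 min_mean_count: float = 3.0,
                 max_zero_fraction: float = 0.75,
                 min_cv: float = 0.3,
                 cv_on: str = "tpm") -> FilterReport:
    """Apply the three sequential expression filters.

    A gene survives iff mean raw count >= ``min_mean_count``, its
    zero-count fraction <= ``max_zero_fraction``, and its coefficient of
    variation (sd/mean) >= ``min_cv``. The CV is computed on TPM by
    default (``cv_on="tpm"``) since that is the expression unit of the
    analysis; pass ``cv_on="count"`` to use raw counts. The report
    itemizes removals in the stated order, so each gene is charged to the
    first rule it fails.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise BudphaseError("cannot filter an empty expression matrix")
    if cv_on not in ("tpm", "count"):
        raise BudphaseError("cv_on must be 'tpm' or 'count'")
    if cv_on == "tpm":
        if tpm is None:
            raise BudphaseError("TPM matrix required when cv_on='tpm'")
        if not counts.gene_ids.equals(tpm.gene_ids) or \
                not counts.sample_ids.equals(tpm.sample_ids):
            raise BudphaseError("counts and TPM must share gene and sample ids")
        cv_values = tpm.values.to_numpy(dtype=float)
    else:
        cv_values = counts.values.to_numpy(dtype=float)

    c = counts.values.to_numpy(dtype=float)
    mean_count = c.mean(axis=1)
    zero_frac = (c == 0).mean(axis=1)
    mean_cv = cv_values.mean(axis=1)
    sd_cv = cv_values.std(axis=1, ddof=1) if c.shape[1] > 1 else np.zeros(c.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean_cv > 0, sd_cv / mean_cv, 0.0)

    low_expr = mean_count < min_mean_count
    mostly_zero = ~low_expr & (zero_frac > max_zero_fraction)
    low_cv = ~low_expr & ~mostly_zero & (cv < min_cv)
    surviving = ~(low_expr | mostly_zero | low_cv)
    return FilterReport(
        n_input=c.shape[0],
        n_low_expression_removed=int(low_expr.sum()),
        n_mostly_zero_removed=int(mostly_zero.sum()),
        n_low_cv_removed=int(low_cv.sum()),
        surviving_gene_ids=counts.gene_ids[surviving],
    )


def call_degs(tpm: ExpressionMatrix,
              metadata: pd.DataFrame,
              dormant_stages=DEFAULT_DORMANT_STAGES,
              alpha: float = 0.05) -> pd.DataFrame:
    """Two-group Welch test on log2(TPM+1), BH-adjusted.

    Splits samples into dormant (stage in ``dormant_stages``) and
    non-dormant groups, tests every gene, and flags genes with adjusted
    p < ``alpha``. Deterministic given its inputs.

    Returns a DataFrame with columns
    ``gene_id log2fc pvalue padj is_deg`` (log2fc = dormant minus
    non-dormant mean of log2(TPM+1)).
    """
    dormant_stages = set(dormant_stages)
    unknown = dormant_stages - set(STAGES)
    if unknown:
        raise BudphaseError(f"unknown stages in dormant_stages: {sorted(unknown)}")
    meta = metadata.set_index("sample_id").loc[tpm.sample_ids]
    is_dormant = meta["stage"].isin(dormant_stages).to_numpy()
    n_a, n_b = int(is_dormant.sum()), int((~is_dormant).sum())
    if n_a < 2 or n_b < 2:
        raise BudphaseError(
            f"each group needs >= 2 samples (dormant={n_a}, non-dormant={n_b})")

    logx = np.log2(tpm.values.to_numpy(dtype=float) + 1.0)
    a, b = logx[:, is_dormant], logx[:, ~is_dormant]
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    # Genes constant in both groups have undefined t statistics; they show
    # no difference, so assign p = 1.
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    padj = bh_adjust(pvals)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame({
        "gene_id": tpm.gene_ids,
        "log2fc": log2fc,
        "pvalue": pvals,
        "padj": padj,
        "is_deg": padj < alpha,
    }).reset_index(drop=True)


def read_deg_table(path) -> pd.DataFrame:
    """Read an externally produced DEG table (TSV, same schema as ours)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue", "padj", "is_deg"}
    missing = required - set(df.columns)
    if missing:
        raise BudphaseError(f"DEG table missing columns: {sorted(missing)}")
    return df


def write_deg_table(degs: pd.DataFrame, path) -> None:
    degs.to_csv(path, sep="\t", index=False)
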