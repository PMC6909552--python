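"""Core data containers: expression matrices and sample metadata.

The package works on gene-level bulk RNA-seq time courses of perennial
flower buds. Expression lives in an :class:`ExpressionMatrix` (genes x
samples, raw counts or TPM); per-sample information (cultivar, tree
replicate, sampling date, optional dormancy-stage label) lives in a plain
pandas DataFrame validated by :func:`validate_metadata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five flower-bud stages, in chronological order over a dormancy cycle.
STAGES: tuple[str, ...] = (
    "organogenesis",
    "paradormancy",
    "endodormancy",
    "dormancy_release",
    "ecodormancy",
)

#: Chronological rank of each stage (used for ordered tie-breaks and
#: chronology-consistency checks).
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

TPM_SCALE = 1.0e6
_TPM_RTOL = 1.0e-9

METADATA_COLUMNS = ("sample_id", "cultivar", "tree", "date", "stage")


class BudphaseError(ValueError):
    """Base class for domain validation errors."""


@dataclass
class ExpressionMatrix:
    """Gene-level expression, genes x samples.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative expression values; index = gene ids, columns = sample
        ids.
    unit : {"count", "TPM"}
        Raw read counts or transcripts per million. TPM columns must each
        sum to 1e6 (relative tolerance 1e-9).
    gene_lengths : pandas.Series, optional
        Gene lengths in bp, indexed by gene id; required for TPM
        computation.
    """

    values: pd.DataFrame
    unit: str = "count"
    gene_lengths: pd.Series | None = field(default=None)
    #: Gene subsets of a TPM matrix are no longer full-library TPM; the
    #: column-sum invariant is skipped for them (set by subset_genes).
    validate_sums: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.unit not in ("count", "TPM"):
            raise BudphaseError(f"unit must be 'count' or 'TPM', got {self.unit!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise BudphaseError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise BudphaseError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise BudphaseError("expression values must be finite")
        if (arr < 0).any():
            raise BudphaseError("expression values must be non-negative")
        if self.unit == "TPM" and self.validate_sums and arr.size:
            colsums = arr.sum(axis=0)
            if not np.allclose(colsums, TPM_SCALE, rtol=_TPM_RTOL, atol=0.0):
                bad = self.values.columns[
                    ~np.isclose(colsums, TPM_SCALE, rtol=_TPM_RTOL, atol=0.0)
                ].tolist()
                raise BudphaseError(f"TPM columns must sum to 1e6; offending samples: {bad[:5]}")
        if self.gene_lengths is not None:
            self.gene_lengths = pd.Series(self.gene_lengths).astype(int)
            missing = self.values.index.difference(self.gene_lengths.index)
            if len(missing):
                raise BudphaseError(f"missing gene length for: {missing.tolist()[:5]}")
            lengths = self.gene_lengths.loc[self.values.index]
            if (lengths <= 0).any():
                bad = lengths.index[lengths <= 0].tolist()
                raise BudphaseError(f"gene lengths must be positive: {bad[:5]}")
            self.gene_lengths = lengths

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = pd.Index(gene_ids)
        missing = gene_ids.difference(self.values.index)
        if len(missing):
            raise BudphaseError(f"unknown gene ids: {missing.tolist()[:5]}")
        lengths = None if self.gene_lengths is None else self.gene_lengths.loc[gene_ids]
        return ExpressionMatrix(self.values.loc[gene_ids], self.unit, lengths,
                                validate_sums=False)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = pd.Index(sample_ids)
        missing = sample_ids.difference(self.values.columns)
        if len(missing):
            raise BudphaseError(f"unknown sample ids: {missing.tolist()[:5]}")
        return ExpressionMatrix(self.values[sample_ids], self.unit,
                                self.gene_lengths,
                                validate_sums=self.validate_sums)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, unit: str = "count", gene_lengths: pd.Series | None = None
                 ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df, unit=unit, gene_lengths=gene_lengths)


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column TSV ``gene_id<TAB>length_bp``."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise BudphaseError("gene length table needs columns gene_id, length_bp")
    df.columns = ["gene_id", "length_bp", *df.columns[2:]]
    return df.set_index("gene_id")["length_bp"].astype(int)


def write_gene_lengths(lengths: pd.Series, path) -> None:
    out = lengths.rename("length_bp").rename_axis("gene_id").reset_index()
    out.to_csv(path, sep="\t", index=False)


def validate_metadata(metadata: pd.DataFrame,
                      sample_ids: pd.Index | None = None) -> pd.DataFrame:
    """Validate and normalize a sample-metadata table.

    Ensures the columns ``sample_id cultivar tree date stage``, ISO dates,
    unique sample ids, stage labels among the five categories (empty/NaN
    allowed), and — when ``sample_ids`` is given — exactly one record per
    expression sample.
    """
    metadata = metadata.copy()
    for col in ("sample_id", "cultivar", "tree", "date"):
        if col not in metadata.columns:
            raise BudphaseError(f"metadata missing required column {col!r}")
    if "stage" not in metadata.columns:
        metadata["stage"] = pd.NA
    if metadata["sample_id"].duplicated().any():
        dups = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise BudphaseError(f"duplicate metadata sample ids: {dups[:5]}")
    try:
        metadata["date"] = pd.to_datetime(metadata["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise BudphaseError(f"metadata dates must be ISO 8601: {exc}") from exc
    stages = metadata["stage"]
    bad = stages.dropna()
    bad = bad[(bad != "") & ~bad.isin(STAGES)]
    if len(bad):
        raise BudphaseError(f"unknown stage labels: {sorted(set(bad))}")
    metadata["stage"] = stages.replace("", pd.NA)
    if sample_ids is not None:
        missing = pd.Index(sample_ids).difference(metadata["sample_id"])
        if len(missing):
            raise BudphaseError(f"samples without metadata: {missing.tolist()[:5]}")
    return metadata[list(METADATA_COLUMNS)]


def read_metadata(path, sample_ids: pd.Index | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cultivar": str,
                                            "tree": str, "stage": str})
    return validate_metadata(df, sample_ids=sample_ids)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)
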