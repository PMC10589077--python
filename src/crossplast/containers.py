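"""Core in-memory containers shared across the pipeline.

A :class:`CountMatrix` bundles an integer gene × sample count table with
per-sample metadata (condition plus a blocking factor such as family or
timepoint).  An :class:`ExpressionMatrix` carries derived abundances (TPM
or log2-CPM) on the same axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "ExpressionMatrix", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input table violates the pipeline's contracts."""


@dataclass
class CountMatrix:
    """Gene-level RNA-seq counts (genes × samples) with sample metadata.

    Parameters
    ----------
    counts
        Integer DataFrame, rows indexed by gene id, columns by sample id.
    sample_meta
        DataFrame indexed by sample id.  Must contain a ``condition``
        column; any further columns (``block``, ``timepoint``) are
        treated as blocking factors.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dupes[:5])}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0, rtol=0):
                bad = np.argwhere(values != np.round(values))
                g, s = bad[0]
                raise ValidationError(
                    "non-integer count at gene "
                    f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("negative counts present")
        if "condition" not in self.sample_meta.columns:
            raise ValidationError("sample_meta lacks a 'condition' column")
        missing = self.counts.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValidationError(f"samples missing from metadata: {list(missing[:5])}")
        # align metadata rows to count columns; standardize axis names so
        # round-tripping through TSV preserves frame equality
        self.sample_meta = self.sample_meta.loc[self.counts.columns]
        self.counts.index.name = "gene"
        self.counts.columns.name = None
        self.sample_meta.index.name = "sample"

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(
            counts=self.counts.loc[:, sample_ids].copy(),
            sample_meta=self.sample_meta.loc[sample_ids].copy(),
        )

    def subset_genes(self, gene_ids) -> "CountMatrix":
        gene_ids = [g for g in self.gene_ids if g in set(gene_ids)]
        return CountMatrix(
            counts=self.counts.loc[gene_ids].copy(),
            sample_meta=self.sample_meta.copy(),
        )


@dataclass
class ExpressionMatrix:
    """Real-valued expression table tagged with its unit (``tpm`` or ``log2cpm``)."""

    values: pd.DataFrame
    kind: str
    sample_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("tpm", "log2cpm"):
            raise ValidationError(f"unknown expression kind {self.kind!r}")
        if self.kind == "log2cpm" and not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("log2-CPM values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns
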