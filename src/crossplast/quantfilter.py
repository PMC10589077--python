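"""Abundance units, the low-expression filter, and MDS sample ordination.

TPM (transcripts per million) length-normalizes counts so that transcript
molar abundances are comparable across genes; genes whose abundance falls
below 1 TPM are conventionally excluded as biologically dubious.  The
retained gene set is the species' "expression-filtered universe" — the
sampling frame for the downstream overlap permutation test.  log2-CPM is
the library-size-normalized unit used for QC ordination and fold-change
visualisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, ValidationError

__all__ = [
    "compute_tpm",
    "filter_low_expression",
    "log2_cpm",
    "mds_coordinates",
    "aggregate_transcripts",
]

FILTER_RULES = ("mean", "all-samples", "any-sample")


def compute_tpm(counts: CountMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts per million from counts and per-gene effective lengths.

    Per sample, ``rate_g = count_g / length_g`` and
    ``TPM_g = 1e6 * rate_g / sum(rates)``.  An all-zero sample yields an
    all-zero column rather than an error.
    """
    missing = counts.gene_ids.difference(lengths.index)
    if len(missing):
        raise ValidationError(f"genes without a length: {list(missing[:10])}")
    lens = lengths.loc[counts.gene_ids].astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0]
        raise ValidationError(f"non-positive lengths for genes: {list(bad[:10])}")
    rates = counts.counts.div(lens, axis=0)
    totals = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rates.div(totals, axis=1) * 1e6
    tpm = tpm.fillna(0.0)  # all-zero columns
    return ExpressionMatrix(values=tpm, kind="tpm", sample_meta=counts.sample_meta)


def filter_low_expression(
    tpm: ExpressionMatrix, threshold: float = 1.0, rule: str = "mean"
) -> pd.Index:
    """Return the gene ids retained by the <``threshold`` TPM exclusion.

    ``rule`` decides how per-sample TPMs are aggregated before comparison:
    ``mean`` (default) keeps genes whose mean TPM across samples is >=
    threshold; ``all-samples`` requires every sample to reach it;
    ``any-sample`` requires at least one.  The boundary is inclusive: a
    gene at exactly the threshold is retained (only strictly lower
    abundance is excluded).
    """
    if tpm.kind != "tpm":
        raise ValidationError("filter_low_expression expects a TPM matrix")
    if rule not in FILTER_RULES:
        raise ValidationError(f"unknown filter rule {rule!r}; choose from {FILTER_RULES}")
    if rule == "mean":
        keep = tpm.values.mean(axis=1) >= threshold
    elif rule == "all-samples":
        keep = (tpm.values >= threshold).all(axis=1)
    else:
        keep = (tpm.values >= threshold).any(axis=1)
    retained = tpm.values.index[keep]
    if len(retained) == 0:
        import warnings

        warnings.warn("expression filter retained no genes", stacklevel=2)
    return retained


def log2_cpm(
    counts: CountMatrix,
    prior_count: float = 2.0,
    norm_factors: pd.Series | None = None,
) -> ExpressionMatrix:
    """log2 counts per million with a library-size-proportional prior count.

    The prior for sample *s* is ``prior_count * L_s / mean(L)`` where
    ``L_s`` is its effective library size (raw size times its
    normalization factor if given); the denominator is ``L_s + 2 * prior_s``.
    This keeps zero counts finite and comparable across libraries of
    different depth.
    """
    lib = counts.library_sizes().astype(float)
    if norm_factors is not None:
        lib = lib * norm_factors.loc[lib.index]
    if (lib <= 0).any():
        raise ValidationError("library sizes must be positive for log2-CPM")
    prior = prior_count * lib / lib.mean()
    adj = counts.counts.add(prior, axis=1)
    denom = lib + 2.0 * prior
    vals = np.log2(adj.div(denom, axis=1) * 1e6)
    return ExpressionMatrix(values=vals, kind="log2cpm", sample_meta=counts.sample_meta)


def mds_coordinates(
    expr: ExpressionMatrix, n_top_genes: int = 500, n_dims: int = 2
) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on Euclidean log2-CPM distances.

    Distances are computed over the ``n_top_genes`` most variable genes.
    Coordinates are centered at the origin and ordered by decreasing
    eigenvalue, so dimension 1 carries the largest share of variation.
    Exact Euclidean input in ``n_dims`` dimensions is reconstructed up to
    rotation/reflection.
    """
    n = len(expr.sample_ids)
    if n < 3:
        raise ValidationError("MDS requires at least 3 samples")
    if n < n_dims + 1:
        raise ValidationError(f"need at least n_dims + 1 = {n_dims + 1} samples, got {n}")
    mat = expr.values
    if mat.shape[0] > n_top_genes:
        variances = mat.var(axis=1)
        top = variances.sort_values(ascending=False).index[:n_top_genes]
        mat = mat.loc[top]
    X = mat.to_numpy().T  # samples × genes
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    # double centering: B = -1/2 J D^2 J
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:n_dims]
    lam = np.clip(eigval[order], 0.0, None)
    # numerically-zero eigenvalues span a noise subspace; zero them out
    lam[lam < 1e-12 * max(lam.max(), 1.0)] = 0.0
    coords = eigvec[:, order] * np.sqrt(lam)[None, :]
    return pd.DataFrame(
        coords,
        index=expr.sample_ids,
        columns=[f"dim{i + 1}" for i in range(n_dims)],
    )


def aggregate_transcripts(
    transcript_counts: pd.DataFrame, tx2gene: pd.Series
) -> pd.DataFrame:
    """Sum transcript-level counts to gene level via a transcript→gene map."""
    missing = transcript_counts.index.difference(tx2gene.index)
    if len(missing):
        raise ValidationError(
            f"transcripts without a gene mapping: {list(missing[:10])}"
        )
    genes = tx2gene.loc[transcript_counts.index]
    return transcript_counts.groupby(genes.to_numpy()).sum()
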