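"""Readers and writers for the pipeline's plain-text formats.

Counts and lengths travel as TSV; DEG lists and universes as one id per
line; ortholog pairs as 2-column TSV; permutation histograms as
(overlap, frequency) TSV.  Gene identifiers are opaque, case-sensitive
strings throughout — no symbol normalization is attempted.
"""

from __future__ import annotations

import hashlib
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_lengths",
    "read_gene_list",
    "write_gene_list",
    "write_de_result",
    "read_de_result",
    "write_pairs",
    "read_pairs",
    "write_histogram",
    "load_shared_deg_reference",
    "shared_deg_tallies",
]

SHARED_DEG_SHA256 = "4649f7234f8841f8a4565733a59075992dcfd5c928dce1e349afce0962dcb667"


def read_count_matrix(path, sample_sheet_path) -> CountMatrix:
    """Load a genes × samples count TSV plus its sample sheet.

    The sheet (columns ``sample``, ``condition``, and ``block`` or
    ``timepoint``) fixes the sample order; matrix columns are reordered
    to it when they differ.  Non-integer cells and duplicated gene ids
    are rejected with coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    if "sample" not in sheet.columns or "condition" not in sheet.columns:
        raise ValidationError(f"{sample_sheet_path}: sheet needs 'sample' and 'condition' columns")
    sheet = sheet.set_index("sample")
    missing = sheet.index.difference(raw.columns)
    if len(missing):
        raise ValidationError(f"samples in sheet but not in matrix: {list(missing[:5])}")
    if list(raw.columns) != list(sheet.index):
        logger.info("reordering count columns to sample-sheet order")
        raw = raw.loc[:, sheet.index]
    return CountMatrix(counts=raw, sample_meta=sheet)


def write_count_matrix(cm: CountMatrix, counts_path, sample_sheet_path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    cm.sample_meta.rename_axis("sample").to_csv(sample_sheet_path, sep="\t")


def read_lengths(path) -> pd.Series:
    """Two-column TSV: gene id, effective length in bp."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need gene and length columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="length")
    if s.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene ids in length table")
    return s


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_de_result(result: pd.DataFrame, path) -> None:
    result.rename_axis("gene").to_csv(path, sep="\t")


def read_de_result(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df["tested"] = df["tested"].astype(bool)
    return df


def write_pairs(pairs, path) -> None:
    pd.DataFrame(list(pairs), columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False)]


def write_histogram(perm_overlaps: np.ndarray, path) -> None:
    """Permutation histogram as a (overlap value, frequency) TSV."""
    vals, freq = np.unique(np.asarray(perm_overlaps), return_counts=True)
    pd.DataFrame({"overlap": vals, "frequency": freq}).to_csv(path, sep="\t", index=False)


def load_shared_deg_reference() -> pd.DataFrame:
    """Curated reference table of cross-species shared DEGs.

    53 rows, one per (gene, reference-species treatment timepoint):
    human gene symbol, gene name, the reference species' treatment
    (24 h / 48 h / 72 h low water vs the shared high-water control),
    both species' log2 fold changes and p-values, the higher-expression
    side in each species (HW/LW and C/O), and a flag for genes recurring
    in more than one treatment.  A SHA-256 checksum guards the packaged
    transcription against corruption.
    """
    ref = resources.files("crossplast").joinpath("data/shared_degs_reference.tsv")
    payload = ref.read_bytes()
    digest = hashlib.sha256(payload).hexdigest()
    if digest != SHARED_DEG_SHA256:
        raise ValidationError(
            "shared-DEG reference table failed its checksum; the packaged file is corrupted"
        )
    import io as _stdlib_io

    df = pd.read_csv(_stdlib_io.BytesIO(payload), sep="\t")
    df["repeated"] = df["repeated"].astype(bool)
    return df


def shared_deg_tallies(table: pd.DataFrame | None = None) -> dict:
    """Per-treatment shared-DEG counts and the cross-treatment unique-gene count."""
    if table is None:
        table = load_shared_deg_reference()
    per_treatment = table.groupby("treatment")["gene_id"].size().to_dict()
    unique_genes = int(table["gene_id"].nunique())
    repeated_flagged = set(table.loc[table["repeated"], "gene_id"])
    counts = table.groupby("gene_id")["treatment"].nunique()
    repeated_actual = set(counts.index[counts >= 2])
    return {
        "per_treatment": per_treatment,
        "unique_genes": unique_genes,
        "repeated_flag_consistent": repeated_flagged == repeated_actual,
        "n_rows": int(len(table)),
    }
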