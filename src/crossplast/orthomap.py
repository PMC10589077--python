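"""Reciprocal-best-hit (RBH) ortholog mapping from tabular alignment hits.

Consumes 12-column, outfmt-6-style hit tables (any BLAST-like aligner)
in both query directions and pairs genes across two species when each is
the other's top-scoring hit.  Alignment execution is out of scope;
inputs must already be at the analysis (gene) level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .containers import ValidationError

__all__ = ["OUTFMT6_COLUMNS", "OrthologMap", "read_hit_table", "best_hits", "build_rbh_map"]

logger = logging.getLogger(__name__)

OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

_NUMERIC = {
    "pident": float,
    "length": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "evalue": float,
    "bitscore": float,
}


@dataclass(frozen=True)
class OrthologMap:
    """Strict one-to-one cross-species gene pairs supported by reciprocal best hits."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        a_genes = [a for a, _ in self.pairs]
        b_genes = [b for _, b in self.pairs]
        if len(set(a_genes)) != len(self.pairs) or len(set(b_genes)) != len(self.pairs):
            raise ValidationError("ortholog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    @property
    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def restrict(self, universe_a, universe_b) -> "OrthologMap":
        ua, ub = set(universe_a), set(universe_b)
        return OrthologMap(
            pairs=tuple((a, b) for a, b in self.pairs if a in ua and b in ub)
        )

    def transpose(self) -> "OrthologMap":
        return OrthologMap(pairs=tuple((b, a) for a, b in self.pairs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["gene_a", "gene_b"])


def read_hit_table(
    path, evalue_max: float = 1e-5, strict: bool = True
) -> pd.DataFrame:
    """Parse a 12-column tab-separated hit table, keeping hits with
    ``evalue <= evalue_max``.

    With ``strict=True`` a malformed row (wrong column count or
    unparseable number) raises with its 1-based line number; with
    ``strict=False`` such rows are skipped and logged.
    """
    rows: list[list] = []
    bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                msg = f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                if strict:
                    raise ValidationError(f"{path}: {msg}")
                logger.warning("%s: %s (skipped)", path, msg)
                bad += 1
                continue
            try:
                row = [
                    conv(fields[i]) if (conv := _NUMERIC.get(col)) else fields[i]
                    for i, col in enumerate(OUTFMT6_COLUMNS)
                ]
            except ValueError as exc:
                msg = f"line {lineno}: {exc}"
                if strict:
                    raise ValidationError(f"{path}: {msg}") from exc
                logger.warning("%s: %s (skipped)", path, msg)
                bad += 1
                continue
            rows.append(row)
    if bad:
        logger.warning("%s: skipped %d malformed rows", path, bad)
    hits = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    if hits.empty:
        warnings.warn(f"{path}: no hits parsed", stacklevel=2)
        return hits
    if (hits["evalue"] < 0).any():
        raise ValidationError(f"{path}: negative E-values present")
    return hits[hits["evalue"] <= evalue_max].reset_index(drop=True)


def best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: max bitscore, ties broken by min E-value,
    then max percent identity, then lexicographically smallest subject id.

    Multiple HSPs for one query–subject pair are collapsed to their
    single best HSP first (no HSP score summing).
    """
    if hits.empty:
        return {}
    ordered = hits.sort_values(
        by=["qseqid", "bitscore", "evalue", "pident", "sseqid"],
        ascending=[True, False, True, False, True],
        kind="mergesort",
    )
    # collapsing HSPs to the best one per (q, s) is implied: the first row
    # per query under this ordering is also the best HSP of its pair
    first = ordered.drop_duplicates(subset="qseqid", keep="first")
    return dict(zip(first["qseqid"], first["sseqid"]))


def build_rbh_map(
    best_a_to_b: dict[str, str], best_b_to_a: dict[str, str]
) -> OrthologMap:
    """Pair (a, b) kept iff a's best hit is b and b's best hit is a."""
    pairs = tuple(
        sorted(
            (a, b)
            for a, b in best_a_to_b.items()
            if best_b_to_a.get(b) == a
        )
    )
    return OrthologMap(pairs=pairs)
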