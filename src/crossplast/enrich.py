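"""Over-representation analysis (ORA) of gene lists against GMT collections.

For each gene set, the overlap with the query list is scored with the
hypergeometric upper tail (one-sided: at least the observed overlap when
drawing the query uniformly from the background), followed by
Benjamini–Hochberg FDR across sets.  This is a self-contained,
deterministic enrichment test over offline GMT collections; with live,
versioned annotation databases and other correction schemes, enriched
term lists will differ term-for-term from any particular web service.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .containers import ValidationError
from .detest import bh_adjust

__all__ = ["GeneSetCollection", "read_gmt", "ora_test"]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with a source tag each, plus an optional background.

    When a background is declared, members outside it are dropped (the
    count of dropped ids is logged); set names must be unique.
    """

    sets: dict[str, frozenset]
    sources: dict[str, str]
    background: frozenset | None = None

    def restrict(self, background) -> "GeneSetCollection":
        bg = frozenset(background)
        new_sets = {}
        dropped = 0
        for name, members in self.sets.items():
            kept = members & bg
            dropped += len(members) - len(kept)
            new_sets[name] = kept
        if dropped:
            logger.info("restricted collection to background: dropped %d member ids", dropped)
        return GeneSetCollection(sets=new_sets, sources=dict(self.sources), background=bg)


def read_gmt(path, background=None) -> GeneSetCollection:
    """Parse a GMT file (name, description, members, tab-separated).

    Duplicate member ids within a set are collapsed; a duplicate set
    name or a line with fewer than 3 fields raises with its line number.
    """
    sets: dict[str, frozenset] = {}
    sources: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT lines need name, description and "
                    f">= 1 member, got {len(fields)} fields"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(m for m in fields[2:] if m)
            sources[name] = desc
    coll = GeneSetCollection(sets=sets, sources=sources, background=None)
    if background is not None:
        coll = coll.restrict(background)
    return coll


def ora_test(
    query,
    collection: GeneSetCollection,
    background,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``query`` in each set.

    Per set, ``p = P[X >= k]`` with X hypergeometric(N=|background|,
    K=|set ∩ background|, n=|query|) and k the observed overlap.  BH
    q-values are computed across the sets with overlap >= ``min_overlap``
    (others carry NaN q).  Returns one row per set, sorted by p.
    """
    background = frozenset(background)
    query = frozenset(query)
    if not query <= background:
        raise ValidationError("query is not a subset of the background")
    if not query:
        warnings.warn("empty query: no enrichment computed", stacklevel=2)
        return pd.DataFrame(
            columns=["set", "source", "k", "K", "n", "N", "p_value", "q_value"]
        )
    N = len(background)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        members = members & background
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set": name,
                "source": collection.sources.get(name, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        result["q_value"] = []
        return result
    eligible = result["k"] >= min_overlap
    q = pd.Series(float("nan"), index=result.index)
    if eligible.any():
        q[eligible] = bh_adjust(result.loc[eligible, "p_value"].to_numpy())
    result["q_value"] = q
    return result.sort_values(["p_value", "set"], kind="mergesort").reset_index(drop=True)
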