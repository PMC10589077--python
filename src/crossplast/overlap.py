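"""Cross-species DEG overlap: counting, classification, and permutation null.

Given the expression-filtered gene universes of a focal species A and a
reference species B, their DEG sets, and a one-to-one ortholog map, this
module (1) counts mapped ortholog pairs DE in both species, (2)
classifies each focal DEG as shared / not-significant-in-reference /
unaligned / mapped-but-untested, and (3) asks whether the observed
overlap exceeds chance by drawing DEG-sized gene sets uniformly without
replacement from each universe and recounting the mapped overlap.  A
closed-form mean and variance of the null overlap serve as an analytic
oracle for the permutation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ValidationError
from .orthomap import OrthologMap

__all__ = [
    "OverlapInput",
    "OverlapReport",
    "classify_degs",
    "overlap_count",
    "permutation_test",
    "expected_overlap",
    "concordance_table",
    "overlap_report",
]


@dataclass
class OverlapInput:
    """Universes, DEG sets, and the ortholog map restricted to them."""

    universe_a: frozenset
    universe_b: frozenset
    deg_a: frozenset
    deg_b: frozenset
    pairs: OrthologMap

    def __init__(self, universe_a, universe_b, deg_a, deg_b, pairs: OrthologMap):
        self.universe_a = frozenset(universe_a)
        self.universe_b = frozenset(universe_b)
        self.deg_a = frozenset(deg_a)
        self.deg_b = frozenset(deg_b)
        if not self.deg_a <= self.universe_a:
            raise ValidationError("deg_a is not a subset of universe_a")
        if not self.deg_b <= self.universe_b:
            raise ValidationError("deg_b is not a subset of universe_b")
        self.pairs = pairs.restrict(self.universe_a, self.universe_b)

    @property
    def n_a(self) -> int:
        return len(self.deg_a)

    @property
    def n_b(self) -> int:
        return len(self.deg_b)

    @property
    def big_n_a(self) -> int:
        return len(self.universe_a)

    @property
    def big_n_b(self) -> int:
        return len(self.universe_b)

    @property
    def n_mapped(self) -> int:
        return len(self.pairs)


@dataclass
class OverlapReport:
    """Observed overlap, three-way classification, and the permutation null."""

    observed_overlap: int
    class_shared: frozenset
    class_not_sig: frozenset
    class_unaligned: frozenset
    class_untested: frozenset
    perm_overlaps: np.ndarray | None = None
    p_empirical: float | None = None
    p_add_one: float | None = None
    expected_mean: float | None = None
    expected_var: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    concordance: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> dict:
        out = {
            "observed_overlap": self.observed_overlap,
            "n_shared": len(self.class_shared),
            "n_not_sig": len(self.class_not_sig),
            "n_unaligned": len(self.class_unaligned),
            "n_untested": len(self.class_untested),
            "p_empirical": self.p_empirical,
            "p_add_one": self.p_add_one,
            "expected_mean": self.expected_mean,
            "expected_var": self.expected_var,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        return out


def overlap_count(deg_a, deg_b, pairs: OrthologMap) -> int:
    """Number of ortholog pairs whose members are DE in both species."""
    da, db = set(deg_a), set(deg_b)
    return sum(1 for a, b in pairs.pairs if a in da and b in db)


def classify_degs(inp: OverlapInput, tested_b) -> OverlapReport:
    """Assign each focal DEG to exactly one of four disjoint classes.

    shared: its ortholog is DE in species B; not_sig: its ortholog was
    tested in B but not significant; unaligned: no ortholog in the map;
    untested: mapped but the ortholog was never tested.  The classes
    partition ``deg_a``.
    """
    tested_b = set(tested_b)
    if not tested_b <= inp.universe_b:
        raise ValidationError("tested_b is not a subset of universe_b")
    a_to_b = inp.pairs.a_to_b
    shared, not_sig, unaligned, untested = set(), set(), set(), set()
    for a in inp.deg_a:
        b = a_to_b.get(a)
        if b is None:
            unaligned.add(a)
        elif b in inp.deg_b:
            shared.add(a)
        elif b in tested_b:
            not_sig.add(a)
        else:
            untested.add(a)
    return OverlapReport(
        observed_overlap=len(shared),
        class_shared=frozenset(shared),
        class_not_sig=frozenset(not_sig),
        class_unaligned=frozenset(unaligned),
        class_untested=frozenset(untested),
    )


def permutation_test(
    inp: OverlapInput,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Permutation null of the mapped overlap count.

    Each permutation draws ``n_a`` genes uniformly without replacement
    from universe A and ``n_b`` from universe B — from the full filtered
    universes, ignoring the ortholog map, which only enters when the
    mapped overlap is counted.  The empirical p is the fraction of
    permutations whose overlap equals or exceeds the observed count
    (one-sided, greater).  Identical seeds give identical draws.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    univ_a = sorted(inp.universe_a)
    univ_b = sorted(inp.universe_b)
    idx_a = {g: i for i, g in enumerate(univ_a)}
    idx_b = {g: i for i, g in enumerate(univ_b)}
    pair_a = np.array([idx_a[a] for a, _ in inp.pairs.pairs], dtype=np.int64)
    pair_b = np.array([idx_b[b] for _, b in inp.pairs.pairs], dtype=np.int64)

    observed = overlap_count(inp.deg_a, inp.deg_b, inp.pairs)
    n_a, n_b = inp.n_a, inp.n_b
    big_a, big_b = len(univ_a), len(univ_b)
    perm = np.empty(n_perm, dtype=np.int64)
    in_a = np.zeros(big_a, dtype=bool)
    in_b = np.zeros(big_b, dtype=bool)
    for i in range(n_perm):
        in_a[:] = False
        in_b[:] = False
        in_a[rng.choice(big_a, size=n_a, replace=False)] = True
        in_b[rng.choice(big_b, size=n_b, replace=False)] = True
        perm[i] = int(np.sum(in_a[pair_a] & in_b[pair_b])) if len(pair_a) else 0
    p_emp = float(np.sum(perm >= observed) / n_perm)
    return perm, p_emp


def expected_overlap(inp: OverlapInput) -> tuple[float, float]:
    """Closed-form mean and variance of the permutation-null overlap.

    With M mapped pairs and independent uniform without-replacement draws
    in the two species, each pair is jointly selected with probability
    ``pA * pB`` where ``pA = n_A/N_A``; the mean is ``M * pA * pB``.
    Because the map is injective, two distinct pairs never share a gene,
    so their joint inclusion uses the pairwise without-replacement
    probability ``qA = n_A (n_A - 1) / (N_A (N_A - 1))`` per species:

    ``Var = M pA pB (1 - pA pB) + M (M - 1) (qA qB - (pA pB)^2)``.
    """
    M = inp.n_mapped
    if M == 0:
        return 0.0, 0.0
    pa = inp.n_a / inp.big_n_a
    pb = inp.n_b / inp.big_n_b
    mean = M * pa * pb
    qa = (
        inp.n_a * (inp.n_a - 1) / (inp.big_n_a * (inp.big_n_a - 1))
        if inp.big_n_a > 1
        else 0.0
    )
    qb = (
        inp.n_b * (inp.n_b - 1) / (inp.big_n_b * (inp.big_n_b - 1))
        if inp.big_n_b > 1
        else 0.0
    )
    p_joint = pa * pb
    var = M * p_joint * (1.0 - p_joint) + M * (M - 1) * (qa * qb - p_joint**2)
    return float(mean), float(max(var, 0.0))


def concordance_table(
    shared_a_genes,
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    pairs: OrthologMap,
    contrast_label: str,
    correspondence: int = 1,
    condition_labels_a: tuple[str, str] = ("a", "b"),
    condition_labels_b: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Per-shared-pair fold-change table with concordance flags.

    ``correspondence`` (+1 or -1) declares which orientation of species
    B's contrast "corresponds" to species A's: with +1, a pair is
    concordant when the two logFCs share a sign; with -1 when they
    oppose.  This is a user declaration, never inferred from the data.
    Rows missing a logFC in either species are flagged incomplete.
    """
    if correspondence not in (1, -1):
        raise ValidationError("correspondence must be +1 or -1")
    a_to_b = pairs.a_to_b
    rows = []
    for a in sorted(shared_a_genes):
        b = a_to_b.get(a)
        rec = {
            "gene_a": a,
            "gene_b": b,
            "contrast": contrast_label,
        }
        lfc_a = de_a.at[a, "logFC"] if a in de_a.index else np.nan
        p_a = de_a.at[a, "p_value"] if a in de_a.index else np.nan
        lfc_b = de_b.at[b, "logFC"] if b is not None and b in de_b.index else np.nan
        p_b = de_b.at[b, "p_value"] if b is not None and b in de_b.index else np.nan
        rec.update(logFC_a=lfc_a, p_a=p_a, logFC_b=lfc_b, p_b=p_b)
        incomplete = not (np.isfinite(lfc_a) and np.isfinite(lfc_b))
        rec["incomplete"] = incomplete
        if incomplete:
            rec["higher_in_a"] = None
            rec["higher_in_b"] = None
            rec["concordant"] = None
        else:
            rec["higher_in_a"] = condition_labels_a[1] if lfc_a > 0 else condition_labels_a[0]
            rec["higher_in_b"] = condition_labels_b[1] if lfc_b > 0 else condition_labels_b[0]
            rec["concordant"] = bool(np.sign(lfc_a) * np.sign(lfc_b) * correspondence > 0)
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "contrast",
            "logFC_a",
            "p_a",
            "logFC_b",
            "p_b",
            "higher_in_a",
            "higher_in_b",
            "concordant",
            "incomplete",
        ],
    )


def overlap_report(
    inp: OverlapInput,
    tested_b,
    n_perm: int = 1000,
    seed: int | None = None,
) -> OverlapReport:
    """Classification + permutation test + analytic expectation, in one report.

    Alongside the plain empirical p (fraction of permutations >=
    observed, which can be exactly 0), the add-one estimator
    ``(#{perm >= obs} + 1) / (n_perm + 1)`` is reported as the
    statistically safer companion.
    """
    report = classify_degs(inp, tested_b)
    perm, p_emp = permutation_test(inp, n_perm=n_perm, seed=seed)
    mean, var = expected_overlap(inp)
    report.perm_overlaps = perm
    report.p_empirical = p_emp
    report.p_add_one = float((np.sum(perm >= report.observed_overlap) + 1) / (n_perm + 1))
    report.expected_mean = mean
    report.expected_var = var
    report.n_perm = n_perm
    report.seed = seed
    return report
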