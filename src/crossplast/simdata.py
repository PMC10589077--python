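"""Synthetic two-species RNA-seq data with known cross-species structure.

The generator emulates the statistical skeleton of a two-species
comparative plasticity study: a focal species A assayed as two
discrete morphs across family blocks, and a reference species B assayed
as a shared high-water-style control against several treatment
timepoints.  The two species share a partial 1:1 ortholog catalog
(~56% of the union by default, with ~20–24% of genes private to each
species); counts are negative-binomial with log-normal baseline
abundances, multiplicative family-block effects, library-size
variation, and a mean-dependent dispersion ``phi(mu) = phi0 + a/mu``.
A configurable fraction of genes is truly DE per contrast and a
configurable fraction of DE ortholog pairs is forced to be DE in both
species (``rho_shared``) — the knob that distinguishes shared from
lineage-specific plasticity.  Alignment hit tables encode the true
ortholog map as mutual best hits plus lower-scoring decoy alignments,
and a truth table records every injected effect for parameter-recovery
testing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError
from .orthomap import OUTFMT6_COLUMNS

__all__ = ["SimConfig", "SimTruth", "SimDataset", "simulate_dataset", "write_fixture_bundle"]


class ConfigError(ValidationError):
    """Invalid simulation configuration; the message names the field."""


def _default_samples_a() -> list[tuple[str, str]]:
    return [
        (cond, block)
        for block in ("fam1", "fam2")
        for cond in ("omnivore",) * 3 + ("carnivore",) * 3
    ]


def _default_samples_b() -> list[tuple[str, str]]:
    out = [("control", "hw")] * 3
    for tp in ("24h", "48h", "72h"):
        out += [("treatment", tp)] * 3
    return out


@dataclass
class SimConfig:
    """Tunable parameters of the two-species simulation.

    ``frac_shared_orthologs`` is the shared fraction of the union gene
    catalog; ``logfc_range`` bounds the absolute log2 fold change of
    truly DE genes; ``baseline_logmean_params`` are the (mu, sigma) of
    the log-normal abundance shape; ``dispersion_params`` are
    (phi0, a) of ``phi(mu) = phi0 + a/mu``; ``frac_low_abundance``
    genes are planted below the 1-TPM expression filter.
    """

    n_genes_a: int = 4000
    n_genes_b: int = 3810
    frac_shared_orthologs: float = 0.562
    samples_a: list[tuple[str, str]] = field(default_factory=_default_samples_a)
    samples_b: list[tuple[str, str]] = field(default_factory=_default_samples_b)
    frac_de_a: float = 0.30
    frac_de_b_per_timepoint: float = 0.02
    rho_shared: float = 0.0
    logfc_range: tuple[float, float] = (0.8, 3.0)
    baseline_logmean_params: tuple[float, float] = (4.0, 1.5)
    dispersion_params: tuple[float, float] = (0.05, 2.0)
    libsize_cv: float = 0.2
    seed: int = 0
    # artifact plumbing below: filter/RBH/block machinery exercisers
    frac_low_abundance: float = 0.10
    prob_concordant: float = 0.5
    block_sigma: float = 0.1
    mean_library_size: float = 1.0e6
    decoy_max: int = 2
    inject_ties: bool = False
    n_pathways: int = 20

    def validate(self) -> None:
        for name in (
            "frac_shared_orthologs",
            "frac_de_a",
            "frac_de_b_per_timepoint",
            "rho_shared",
            "frac_low_abundance",
            "prob_concordant",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes_a", "n_genes_b"):
            if getattr(self, name) < 10:
                raise ConfigError(f"{name} must be >= 10, got {getattr(self, name)}")
        lo, hi = self.logfc_range
        if not (0.0 < lo <= hi):
            raise ConfigError(f"logfc_range must satisfy 0 < low <= high, got {self.logfc_range}")
        if self.libsize_cv < 0:
            raise ConfigError(f"libsize_cv must be >= 0, got {self.libsize_cv}")
        if self.mean_library_size <= 0:
            raise ConfigError(f"mean_library_size must be > 0, got {self.mean_library_size}")
        if self.dispersion_params[0] < 0 or self.dispersion_params[1] < 0:
            raise ConfigError(f"dispersion_params must be >= 0, got {self.dispersion_params}")
        conds_a = {c for c, _ in self.samples_a}
        if len(conds_a) != 2:
            raise ConfigError(f"samples_a must use exactly 2 conditions, got {sorted(conds_a)}")
        for cond in conds_a:
            if sum(1 for c, _ in self.samples_a if c == cond) < 2:
                raise ConfigError(f"samples_a needs >= 2 samples of condition {cond!r}")
        conds_b = {c for c, _ in self.samples_b}
        if conds_b != {"control", "treatment"}:
            raise ConfigError(
                f"samples_b conditions must be 'control' and 'treatment', got {sorted(conds_b)}"
            )
        if sum(1 for c, _ in self.samples_b if c == "control") < 2:
            raise ConfigError("samples_b needs >= 2 control samples")
        for tp in self.timepoints_b():
            if sum(1 for c, t in self.samples_b if c == "treatment" and t == tp) < 2:
                raise ConfigError(f"samples_b needs >= 2 treatment samples at timepoint {tp!r}")

    def conditions_a(self) -> tuple[str, str]:
        """The two species-A condition labels in order of first appearance;
        injected fold changes apply to the second (the morph analogue of a
        treatment)."""
        seen: list[str] = []
        for c, _ in self.samples_a:
            if c not in seen:
                seen.append(c)
        return seen[0], seen[1]

    def timepoints_b(self) -> list[str]:
        seen: list[str] = []
        for c, t in self.samples_b:
            if c == "treatment" and t not in seen:
                seen.append(t)
        return seen


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``shared_pairs`` / ``concordant`` are keyed by timepoint and record
    the ortholog pairs DE in both species (forced plus by-chance) and
    whether the two true fold changes share a sign.
    """

    ortholog_pairs: tuple[tuple[str, str], ...]
    de_genes_a: dict[str, float]
    de_genes_b: dict[str, dict[str, float]]
    shared_pairs: dict[str, frozenset]
    concordant: dict[str, dict[tuple[str, str], bool]]
    baseline_tpm_a: pd.Series
    baseline_tpm_b: pd.Series
    low_genes_a: frozenset
    low_genes_b: frozenset
    pathways_a: dict[str, frozenset]


@dataclass
class SimDataset:
    counts_a: CountMatrix
    counts_b: CountMatrix
    lengths_a: pd.Series
    lengths_b: pd.Series
    hits_a_to_b: pd.DataFrame
    hits_b_to_a: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def _baseline_tpm(rng: np.random.Generator, n_genes: int, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """True TPM vector summing to 1e6; a planted fraction sits strictly
    below 1 TPM, the rest strictly above (floor 2 TPM)."""
    n_low = int(round(cfg.frac_low_abundance * n_genes))
    low_mask = np.zeros(n_genes, dtype=bool)
    if n_low:
        low_mask[rng.choice(n_genes, size=n_low, replace=False)] = True
    tpm = np.empty(n_genes)
    tpm[low_mask] = rng.uniform(0.05, 0.6, size=n_low)
    n_keep = n_genes - n_low
    mu, sigma = cfg.baseline_logmean_params
    shape = rng.lognormal(mean=mu, sigma=sigma, size=n_keep)
    floor = 2.0
    budget = 1e6 - tpm[low_mask].sum() - floor * n_keep
    if budget <= 0:
        raise ConfigError("n_genes too large for the TPM floor; reduce gene count")
    tpm[~low_mask] = floor + shape * (budget / shape.sum())
    return tpm, low_mask


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi0: float, a: float) -> np.ndarray:
    phi = phi0 + np.divide(a, np.maximum(mu, 1e-12))
    poisson = phi <= 1e-12
    out = np.empty(mu.shape, dtype=np.int64)
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def _choose_de(
    rng: np.random.Generator,
    eligible_mapped: np.ndarray,
    eligible_unmapped: np.ndarray,
    frac: float,
) -> np.ndarray:
    """Sample DE genes stratified by mapped/unmapped so the realized DE
    fraction among ortholog pairs matches ``frac`` up to rounding."""
    k_m = int(round(frac * eligible_mapped.size))
    k_u = int(round(frac * eligible_unmapped.size))
    picks = []
    if k_m:
        picks.append(rng.choice(eligible_mapped, size=k_m, replace=False))
    if k_u:
        picks.append(rng.choice(eligible_unmapped, size=k_u, replace=False))
    return np.concatenate(picks) if picks else np.array([], dtype=np.int64)


def _hit_rows(
    rng: np.random.Generator,
    query: str,
    subject: str,
    bitscore: float,
    evalue: float,
    pident: float | None = None,
) -> list:
    pident = float(rng.uniform(85.0, 99.9)) if pident is None else pident
    length = int(rng.integers(200, 1500))
    mismatch = int(round(length * (100.0 - pident) / 100.0))
    gapopen = int(rng.integers(0, 4))
    qstart = int(rng.integers(1, 50))
    qend = qstart + length - 1
    sstart = int(rng.integers(1, 50))
    send = sstart + length - 1
    return [query, subject, round(pident, 2), length, mismatch, gapopen,
            qstart, qend, sstart, send, evalue, round(bitscore, 1)]


def simulate_dataset(config: SimConfig | None = None) -> SimDataset:
    """Generate counts, lengths, hit tables and ground truth for two species.

    All randomness flows through a single generator seeded from
    ``config.seed``, so identical configurations reproduce byte-identical
    datasets.
    """
    cfg = config if config is not None else SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes_a = [f"gA{i:05d}" for i in range(cfg.n_genes_a)]
    genes_b = [f"gB{i:05d}" for i in range(cfg.n_genes_b)]

    # --- ortholog catalog: shared fraction of the union -------------------
    n_shared = int(round(
        cfg.frac_shared_orthologs
        * (cfg.n_genes_a + cfg.n_genes_b)
        / (1.0 + cfg.frac_shared_orthologs)
    ))
    n_shared = min(n_shared, cfg.n_genes_a, cfg.n_genes_b)
    mapped_a_idx = rng.choice(cfg.n_genes_a, size=n_shared, replace=False)
    mapped_b_idx = rng.permutation(rng.choice(cfg.n_genes_b, size=n_shared, replace=False))
    pairs = tuple(
        sorted((genes_a[i], genes_b[j]) for i, j in zip(mapped_a_idx, mapped_b_idx))
    )
    partner_b_of_a = {a: b for a, b in pairs}
    mapped_a_set = set(partner_b_of_a)

    # --- baseline abundance, lengths --------------------------------------
    tpm_a, low_a = _baseline_tpm(rng, cfg.n_genes_a, cfg)
    tpm_b, low_b = _baseline_tpm(rng, cfg.n_genes_b, cfg)
    len_a = rng.integers(300, 4001, size=cfg.n_genes_a).astype(np.int64)
    len_b = rng.integers(300, 4001, size=cfg.n_genes_b).astype(np.int64)

    # --- true DE effects ---------------------------------------------------
    lo, hi = cfg.logfc_range
    idx_a = np.arange(cfg.n_genes_a)
    mapped_mask_a = np.isin(idx_a, mapped_a_idx)
    eligible = ~low_a  # DE effects planted only above the expression filter
    de_a_idx = _choose_de(rng, idx_a[eligible & mapped_mask_a], idx_a[eligible & ~mapped_mask_a], cfg.frac_de_a)
    de_a = {
        genes_a[i]: float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))
        for i in sorted(de_a_idx)
    }

    de_a_mapped = sorted(g for g in de_a if g in mapped_a_set)
    timepoints = cfg.timepoints_b()
    kept_b = [genes_b[j] for j in range(cfg.n_genes_b) if not low_b[j]]
    de_b: dict[str, dict[str, float]] = {}
    for tp in timepoints:
        n_de_b = int(round(cfg.frac_de_b_per_timepoint * cfg.n_genes_b))
        n_forced = min(int(round(cfg.rho_shared * len(de_a_mapped))), n_de_b)
        forced_a = (
            list(rng.choice(de_a_mapped, size=n_forced, replace=False)) if n_forced else []
        )
        tp_de: dict[str, float] = {}
        for a in forced_a:
            b = partner_b_of_a[a]
            mag = float(rng.uniform(lo, hi))
            concord = rng.random() < cfg.prob_concordant
            sign = np.sign(de_a[a]) if concord else -np.sign(de_a[a])
            tp_de[b] = float(sign * mag)
        remaining = [g for g in kept_b if g not in tp_de]
        n_rest = max(n_de_b - len(tp_de), 0)
        if n_rest:
            for g in rng.choice(remaining, size=min(n_rest, len(remaining)), replace=False):
                tp_de[g] = float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))
        de_b[tp] = tp_de

    partner_a_of_b = {b: a for a, b in pairs}
    shared_pairs = {
        tp: frozenset(
            (partner_a_of_b[b], b) for b in de_b[tp] if b in partner_a_of_b and partner_a_of_b[b] in de_a
        )
        for tp in timepoints
    }
    concordant = {
        tp: {
            (a, b): bool(np.sign(de_a[a]) == np.sign(de_b[tp][b]))
            for a, b in sorted(shared_pairs[tp])
        }
        for tp in timepoints
    }

    # --- counts: species A -------------------------------------------------
    phi0, a_disp = cfg.dispersion_params
    cond_a1, cond_a2 = cfg.conditions_a()
    blocks_a = sorted({b for _, b in cfg.samples_a})
    block_mult = {
        b: np.exp(rng.normal(0.0, cfg.block_sigma, size=cfg.n_genes_a)) for b in blocks_a
    }
    weight_a = tpm_a * len_a
    frac_reads_a = weight_a / weight_a.sum()
    fc_a = np.ones(cfg.n_genes_a)
    for g, lfc in de_a.items():
        fc_a[int(g[2:])] = 2.0**lfc

    sigma_ls = np.sqrt(np.log1p(cfg.libsize_cv**2))
    counts_a_cols = {}
    meta_a_rows = []
    for i, (cond, block) in enumerate(cfg.samples_a):
        sid = f"sA{i:02d}"
        lib = cfg.mean_library_size * rng.lognormal(-0.5 * sigma_ls**2, sigma_ls)
        mu = lib * frac_reads_a * block_mult[block]
        if cond == cond_a2:
            mu = mu * fc_a
        counts_a_cols[sid] = _nb_counts(rng, mu, phi0, a_disp)
        meta_a_rows.append({"sample": sid, "condition": cond, "block": block})
    counts_a = CountMatrix(
        counts=pd.DataFrame(counts_a_cols, index=genes_a),
        sample_meta=pd.DataFrame(meta_a_rows).set_index("sample"),
    )

    # --- counts: species B -------------------------------------------------
    weight_b = tpm_b * len_b
    frac_reads_b = weight_b / weight_b.sum()
    fc_b = {tp: np.ones(cfg.n_genes_b) for tp in timepoints}
    for tp in timepoints:
        for g, lfc in de_b[tp].items():
            fc_b[tp][int(g[2:])] = 2.0**lfc
    counts_b_cols = {}
    meta_b_rows = []
    for i, (cond, tp) in enumerate(cfg.samples_b):
        sid = f"sB{i:02d}"
        lib = cfg.mean_library_size * rng.lognormal(-0.5 * sigma_ls**2, sigma_ls)
        mu = lib * frac_reads_b
        if cond == "treatment":
            mu = mu * fc_b[tp]
        counts_b_cols[sid] = _nb_counts(rng, mu, phi0, a_disp)
        meta_b_rows.append({"sample": sid, "condition": cond, "timepoint": tp})
    counts_b = CountMatrix(
        counts=pd.DataFrame(counts_b_cols, index=genes_b),
        sample_meta=pd.DataFrame(meta_b_rows).set_index("sample"),
    )

    # --- hit tables: mutual best hits plus lower-scoring decoys ------------
    bits_true = {p: float(rng.uniform(600.0, 1500.0)) for p in pairs}
    ev_true = {p: float(10.0 ** -rng.uniform(60.0, 180.0)) for p in pairs}
    mapped_b_list = sorted(partner_a_of_b)

    def _decoys(table: list, query: str, true_bits: float | None, own_partner: str | None,
                subjects_pool: list[str]) -> None:
        n_dec = int(rng.integers(0, cfg.decoy_max + 1))
        if not subjects_pool or n_dec == 0:
            return
        cap = (true_bits - 1.0) if true_bits is not None else 400.0
        for _ in range(n_dec):
            subj = subjects_pool[int(rng.integers(0, len(subjects_pool)))]
            if subj == own_partner:
                continue
            bits = float(rng.uniform(50.0, max(cap, 51.0)))
            ev = float(10.0 ** -rng.uniform(3.0, 30.0))
            table.append(_hit_rows(rng, query, subj, bits, ev))

    rows_ab: list = []
    rows_ba: list = []
    for a, b in pairs:
        p = (a, b)
        rows_ab.append(_hit_rows(rng, a, b, bits_true[p], ev_true[p]))
        rows_ba.append(_hit_rows(rng, b, a, bits_true[p], ev_true[p]))
    mapped_a_list = sorted(mapped_a_set)
    for i, a in enumerate(genes_a):
        p = (a, partner_b_of_a[a]) if a in partner_b_of_a else None
        _decoys(rows_ab, a, bits_true[p] if p else None, p[1] if p else None, mapped_b_list)
    for j, b in enumerate(genes_b):
        p = (partner_a_of_b[b], b) if b in partner_a_of_b else None
        _decoys(rows_ba, b, bits_true[p] if p else None, p[0] if p else None, mapped_a_list)
    if cfg.inject_ties and pairs:
        # tie on bitscore and evalue, lower identity: exercises the
        # percent-identity tie-break without changing the true best hit
        for a, b in pairs[: max(1, len(pairs) // 50)]:
            other = mapped_b_list[int(rng.integers(0, len(mapped_b_list)))]
            if other == b:
                continue
            row = _hit_rows(rng, a, other, bits_true[(a, b)], ev_true[(a, b)], pident=50.0)
            rows_ab.append(row)

    hits_ab = pd.DataFrame(rows_ab, columns=OUTFMT6_COLUMNS)
    hits_ba = pd.DataFrame(rows_ba, columns=OUTFMT6_COLUMNS)

    # --- pathway labels for the GMT ---------------------------------------
    labels = rng.integers(0, cfg.n_pathways, size=cfg.n_genes_a)
    pathways = {
        f"SIMPATH{k:02d}": frozenset(np.array(genes_a)[labels == k])
        for k in range(cfg.n_pathways)
    }

    truth = SimTruth(
        ortholog_pairs=pairs,
        de_genes_a=de_a,
        de_genes_b=de_b,
        shared_pairs=shared_pairs,
        concordant=concordant,
        baseline_tpm_a=pd.Series(tpm_a, index=genes_a, name="tpm"),
        baseline_tpm_b=pd.Series(tpm_b, index=genes_b, name="tpm"),
        low_genes_a=frozenset(np.array(genes_a)[low_a]),
        low_genes_b=frozenset(np.array(genes_b)[low_b]),
        pathways_a=pathways,
    )
    return SimDataset(
        counts_a=counts_a,
        counts_b=counts_b,
        lengths_a=pd.Series(len_a, index=genes_a, name="length"),
        lengths_b=pd.Series(len_b, index=genes_b, name="length"),
        hits_a_to_b=hits_ab,
        hits_b_to_a=hits_ba,
        truth=truth,
        config=cfg,
    )


def write_fixture_bundle(dataset: SimDataset, out_dir, overwrite: bool = False) -> dict:
    """Write the dataset as plain-text files and return a checksum manifest.

    Refuses to write into a non-empty directory unless ``overwrite`` is
    set.  Regenerating with the same seed reproduces identical checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    existing = [p for p in out.iterdir() if p.name != "manifest.json"]
    if existing and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True to replace")

    from . import io as _io

    ds = dataset
    files: dict[str, Path] = {}

    files["counts_a.tsv"] = out / "counts_a.tsv"
    _io.write_count_matrix(ds.counts_a, files["counts_a.tsv"], out / "samples_a.tsv")
    files["samples_a.tsv"] = out / "samples_a.tsv"
    files["counts_b.tsv"] = out / "counts_b.tsv"
    _io.write_count_matrix(ds.counts_b, files["counts_b.tsv"], out / "samples_b.tsv")
    files["samples_b.tsv"] = out / "samples_b.tsv"
    for name, series in (("lengths_a.tsv", ds.lengths_a), ("lengths_b.tsv", ds.lengths_b)):
        path = out / name
        series.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)
        files[name] = path
    for name, hits in (("hits_a_to_b.tsv", ds.hits_a_to_b), ("hits_b_to_a.tsv", ds.hits_b_to_a)):
        path = out / name
        hits.to_csv(path, sep="\t", index=False, header=False)
        files[name] = path

    gmt = out / "pathways_a.gmt"
    with open(gmt, "w") as fh:
        for name in sorted(ds.truth.pathways_a):
            members = sorted(ds.truth.pathways_a[name])
            if members:
                fh.write("\t".join([name, "simulated_pathway", *members]) + "\n")
    files["pathways_a.gmt"] = gmt

    de_a = out / "truth_de_a.tsv"
    pd.DataFrame(
        sorted(ds.truth.de_genes_a.items()), columns=["gene", "true_logfc"]
    ).to_csv(de_a, sep="\t", index=False)
    files["truth_de_a.tsv"] = de_a
    de_b = out / "truth_de_b.tsv"
    rows = [
        {"timepoint": tp, "gene": g, "true_logfc": lfc}
        for tp in ds.truth.de_genes_b
        for g, lfc in sorted(ds.truth.de_genes_b[tp].items())
    ]
    pd.DataFrame(rows, columns=["timepoint", "gene", "true_logfc"]).to_csv(
        de_b, sep="\t", index=False
    )
    files["truth_de_b.tsv"] = de_b
    pairs_path = out / "truth_pairs.tsv"
    pd.DataFrame(ds.truth.ortholog_pairs, columns=["gene_a", "gene_b"]).to_csv(
        pairs_path, sep="\t", index=False
    )
    files["truth_pairs.tsv"] = pairs_path

    manifest = {
        "seed": ds.config.seed,
        "n_genes_a": ds.config.n_genes_a,
        "n_genes_b": ds.config.n_genes_b,
        "files": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(files.items())
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
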