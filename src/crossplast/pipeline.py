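"""End-to-end driver: filter → DE (both species) → RBH → overlap → ORA.

The pipeline consumes gene-level count matrices with sample sheets, gene
lengths, two directional hit tables, and optionally a GMT collection; it
writes every stage's output as plain text plus a machine-readable
summary (one row per reference-species contrast: DEG counts, universe
sizes, mapped pairs, observed overlap, analytic expectation, empirical
p) and a run manifest with checksums for auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from . import __version__
from .containers import ValidationError
from .detest import Contrast, estimate_dispersions, fit_and_test, tmm_factors
from .enrich import ora_test, read_gmt
from .orthomap import best_hits, build_rbh_map, read_hit_table
from .overlap import OverlapInput, concordance_table, overlap_report
from .quantfilter import compute_tpm, filter_low_expression, log2_cpm, mds_coordinates

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    counts_a: str
    samples_a: str
    counts_b: str
    samples_b: str
    lengths_a: str
    lengths_b: str
    hits_a_to_b: str
    hits_b_to_a: str
    out_dir: str
    gmt: str | None = None
    tpm_threshold: float = 1.0
    filter_rule: str = "mean"
    q_threshold: float = 0.05
    evalue_max: float = 1e-5
    n_perm: int = 1000
    seed: int = 0
    condition_a_ref: str = "omnivore"
    condition_a_alt: str = "carnivore"
    block_a: str | None = "block"
    condition_b_control: str = "control"
    condition_b_treatment: str = "treatment"
    timepoint_column: str = "timepoint"
    correspondence: int = 1

    def validate(self) -> None:
        if not (0.0 < self.q_threshold <= 1.0):
            raise ValidationError("q_threshold must lie in (0, 1]")
        if self.tpm_threshold < 0:
            raise ValidationError("tpm_threshold must be >= 0")
        if self.evalue_max <= 0:
            raise ValidationError("evalue_max must be > 0")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.correspondence not in (1, -1):
            raise ValidationError("correspondence must be +1 or -1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: dict, name: str, t0: float, **counts) -> None:
    elapsed = time.perf_counter() - t0
    manifest["stages"][name] = {"elapsed_s": round(elapsed, 3), **counts}
    logger.info("stage %s done in %.2fs: %s", name, elapsed, counts)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }

    # ---- load ------------------------------------------------------------
    t0 = time.perf_counter()
    cm_a = _io.read_count_matrix(config.counts_a, config.samples_a)
    cm_b = _io.read_count_matrix(config.counts_b, config.samples_b)
    len_a = _io.read_lengths(config.lengths_a)
    len_b = _io.read_lengths(config.lengths_b)
    _stage(manifest, "load", t0, genes_a=cm_a.n_genes, genes_b=cm_b.n_genes,
           samples_a=cm_a.n_samples, samples_b=cm_b.n_samples)

    # ---- expression filter + QC ordination -------------------------------
    t0 = time.perf_counter()
    universes = {}
    for label, cm, lens in (("a", cm_a, len_a), ("b", cm_b, len_b)):
        tpm = compute_tpm(cm, lens)
        universe = filter_low_expression(tpm, config.tpm_threshold, config.filter_rule)
        universes[label] = universe
        _io.write_gene_list(universe, out / f"universe_{label}.txt")
        lcpm = log2_cpm(cm.subset_genes(universe))
        mds = mds_coordinates(lcpm)
        mds.rename_axis("sample").to_csv(out / f"mds_{label}.tsv", sep="\t")
    _stage(manifest, "filter", t0,
           universe_a=len(universes["a"]), universe_b=len(universes["b"]))

    # ---- differential expression -----------------------------------------
    t0 = time.perf_counter()
    sub_a = cm_a.subset_genes(universes["a"])
    contrast_a = Contrast(config.condition_a_ref, config.condition_a_alt, block=config.block_a)
    nf_a = tmm_factors(sub_a.subset_samples(contrast_a.resolve_samples(sub_a)))
    disp_a = estimate_dispersions(sub_a, contrast_a, norm_factors=nf_a)
    de_a = fit_and_test(sub_a, contrast_a, dispersions=disp_a, norm_factors=nf_a,
                        alpha=config.q_threshold)
    _io.write_de_result(de_a, out / "de_a.tsv")
    deg_a = set(de_a.index[(de_a["q_value"] < config.q_threshold) & de_a["tested"]])

    meta_b = cm_b.sample_meta
    timepoints = [
        t for t in meta_b.loc[
            meta_b["condition"] == config.condition_b_treatment, config.timepoint_column
        ].unique()
    ]
    sub_b = cm_b.subset_genes(universes["b"])
    de_b: dict[str, pd.DataFrame] = {}
    for tp in timepoints:
        samples = list(
            meta_b.index[
                (meta_b["condition"] == config.condition_b_control)
                | (
                    (meta_b["condition"] == config.condition_b_treatment)
                    & (meta_b[config.timepoint_column] == tp)
                )
            ]
        )
        contrast = Contrast(
            config.condition_b_control, config.condition_b_treatment, samples=samples
        )
        res = fit_and_test(sub_b, contrast, alpha=config.q_threshold)
        de_b[tp] = res
        _io.write_de_result(res, out / f"de_b_{tp}.tsv")
    _stage(manifest, "de", t0, deg_a=len(deg_a),
           **{f"deg_b_{tp}": int(((de_b[tp]["q_value"] < config.q_threshold)
                                  & de_b[tp]["tested"]).sum()) for tp in timepoints})

    # ---- ortholog map ----------------------------------------------------
    t0 = time.perf_counter()
    hits_ab = read_hit_table(config.hits_a_to_b, evalue_max=config.evalue_max)
    hits_ba = read_hit_table(config.hits_b_to_a, evalue_max=config.evalue_max)
    rbh = build_rbh_map(best_hits(hits_ab), best_hits(hits_ba))
    _io.write_pairs(rbh.pairs, out / "ortholog_pairs.tsv")
    _stage(manifest, "rbh", t0, hits_ab=len(hits_ab), hits_ba=len(hits_ba), pairs=len(rbh))

    # ---- overlap per reference contrast ----------------------------------
    t0 = time.perf_counter()
    summary_rows = []
    for i, tp in enumerate(timepoints):
        res_b = de_b[tp]
        deg_b_tp = set(res_b.index[(res_b["q_value"] < config.q_threshold) & res_b["tested"]])
        tested_b = set(res_b.index[res_b["tested"]]) & set(universes["b"])
        inp = OverlapInput(
            universe_a=universes["a"],
            universe_b=universes["b"],
            deg_a=deg_a,
            deg_b=deg_b_tp & set(universes["b"]),
            pairs=rbh,
        )
        report = overlap_report(inp, tested_b, n_perm=config.n_perm,
                                seed=config.seed + i)
        _io.write_histogram(report.perm_overlaps, out / f"perm_hist_{tp}.tsv")
        conc = concordance_table(
            report.class_shared, de_a, res_b, rbh, contrast_label=str(tp),
            correspondence=config.correspondence,
            condition_labels_a=(config.condition_a_ref, config.condition_a_alt),
            condition_labels_b=(config.condition_b_control, config.condition_b_treatment),
        )
        conc.to_csv(out / f"concordance_{tp}.tsv", sep="\t", index=False)
        summary_rows.append(
            {
                "contrast_b": tp,
                "n_deg_a": inp.n_a,
                "n_deg_b": inp.n_b,
                "universe_a": inp.big_n_a,
                "universe_b": inp.big_n_b,
                "mapped_pairs": inp.n_mapped,
                "observed_overlap": report.observed_overlap,
                "n_not_sig": len(report.class_not_sig),
                "n_unaligned": len(report.class_unaligned),
                "n_untested": len(report.class_untested),
                "expected_overlap": report.expected_mean,
                "p_empirical": report.p_empirical,
                "p_add_one": report.p_add_one,
                "n_perm": config.n_perm,
                "seed": config.seed + i,
            }
        )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "overlap_summary.tsv", sep="\t", index=False)
    _stage(manifest, "overlap", t0, contrasts=len(timepoints))

    # ---- enrichment ------------------------------------------------------
    if config.gmt is not None:
        t0 = time.perf_counter()
        background = set(universes["a"])
        coll = read_gmt(config.gmt, background=background)
        enr = ora_test(deg_a & background, coll, background)
        enr.to_csv(out / "enrichment_a.tsv", sep="\t", index=False)
        _stage(manifest, "enrich", t0, sets=len(coll.sets))

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
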