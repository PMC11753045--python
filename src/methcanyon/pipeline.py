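"""End-to-end orchestration of the synthetic-to-results run.

``run_all`` executes: simulate -> global profiles (2-kb window PCA,
feature-class distributions) -> per-sample canyon calling with group
consensus and unique sets -> promoter differential methylation -> the
cross-platform race-pDMR chain (when an array cohort is configured) ->
CIMP marker check -> optional gene-set overrepresentation.  Every stage
writes its tables before the next stage starts, and a manifest records the
seed, all parameter values and per-stage counts so a run is reproducible
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import promoter_windows
from .canyons import (
    HmmParams, call_umrs, designate_canyons, group_consensus, merge_umrs,
    unique_canyons, annotate_canyons_to_genes,
)
from .crossplat import race_pdmr_pipeline
from .diffmeth import region_dmr_test, top_variable
from .io import drop_chromosome, make_windows, map_to_regions, write_bed, write_methylome
from .profiles import cimp_check, feature_distribution, global_windows_pca, ora_collection, read_gmt
from .simulate import SimulationConfig, simulate_cohorts

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """All knobs of a full run; defaults are the analysis' canonical
    thresholds (coverage >= 4, 2-kb windows, promoter -1000/+500, UMR merge
    gap 500 bp and mean <= 0.1, canyon >= 3.5 kb and < 0.1, consensus >=
    50%, DMR >= 10 CpGs and |delta| >= 0.1, alpha 0.05)."""

    outdir: str = "results"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_coverage: int = 4
    window_bp: int = 2000
    drop_chrom: str = "chrX"
    hmm: HmmParams = field(default_factory=HmmParams)
    merge_gap_bp: int = 500
    merge_max_mean: float = 0.1
    canyon_min_length_bp: int = 3500
    canyon_max_mean: float = 0.1
    consensus_min_frac: float = 0.5
    dmr_min_cpgs: int = 10
    min_delta: float = 0.1
    race_min_delta: float = 0.1
    alpha: float = 0.05
    top_variable_fraction: float = 0.01
    gmt: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        hmm = HmmParams(**raw.pop("hmm", {}))
        cfg = cls(sim=sim, hmm=hmm, **raw)
        cfg.sim.seed = cfg.seed
        return cfg


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_all(config: RunConfig) -> dict:
    """Execute the full chain; returns the results bundle and writes every
    table plus ``manifest.json`` under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}
    results: dict[str, object] = {}
    config.sim.seed = config.seed

    # --- stage 1: simulate -------------------------------------------------
    wgbs, array_matrix, truth, annotation = simulate_cohorts(config.sim)
    simdir = out / "simulated"
    simdir.mkdir(exist_ok=True)
    samples: dict[str, pd.DataFrame] = {}
    groups = {}
    for group, by_sample in wgbs.items():
        for sid, rec in by_sample.items():
            rec = drop_chromosome(rec, config.drop_chrom)
            rec = rec[rec["coverage"] >= config.min_coverage].reset_index(drop=True)
            samples[sid] = rec
            groups[sid] = group
            write_methylome(rec, simdir / f"{sid}.meth.tsv")
    groups = pd.Series(groups)
    truth.canyons.assign(groups=[",".join(g) for g in truth.canyons["groups"]]).to_csv(
        simdir / "truth_canyons.tsv", sep="\t", index=False
    )
    counts["samples"] = len(samples)
    counts["cpgs_per_sample"] = int(np.mean([len(r) for r in samples.values()]))

    # --- stage 2: global profiles -----------------------------------------
    windows = make_windows(annotation.chrom_sizes, config.window_bp)
    windows = drop_chromosome(windows, config.drop_chrom)
    win_mat = map_to_regions(samples, windows, groups=groups)
    scores, evr = global_windows_pca(win_mat)
    _write(scores.assign(group=groups.loc[scores.index]), out / "windows_pca.tsv", index=True)
    results["pca_explained_variance"] = [float(v) for v in evr]
    isl_summary = feature_distribution(samples, annotation.islands)
    _write(isl_summary, out / "island_distribution.tsv", index=True)
    rep_summary = feature_distribution(samples, annotation.repeats)
    _write(rep_summary, out / "repeat_distribution.tsv", index=True)
    counts["windows"] = len(windows)

    # --- stage 3: canyons --------------------------------------------------
    group_names = list(wgbs.keys())
    consensus = {}
    canyons_by_group: dict[str, dict] = {}
    for group in group_names:
        canyons_by_group[group] = {}
        for sid in wgbs[group]:
            umrs = call_umrs(samples[sid], config.hmm, sample=sid)
            merged = merge_umrs(umrs, samples[sid], config.merge_gap_bp, config.merge_max_mean)
            cany = designate_canyons(merged, config.canyon_min_length_bp, config.canyon_max_mean)
            canyons_by_group[group][sid] = cany
        cons = group_consensus(canyons_by_group[group], config.consensus_min_frac)
        consensus[group] = cons
        write_bed(cons, out / f"consensus_canyons_{group}.bed", extra_cols=["support", "n_samples"])
        counts[f"consensus_canyons_{group}"] = len(cons)
    results["consensus"] = consensus
    if len(group_names) >= 2:
        a, b = group_names[-2], group_names[-1]
        a_only, b_only, shared = unique_canyons(consensus[a], consensus[b])
        write_bed(a_only, out / f"unique_canyons_{a}.bed", extra_cols=["support"])
        write_bed(b_only, out / f"unique_canyons_{b}.bed", extra_cols=["support"])
        counts["unique_canyons"] = {a: len(a_only), b: len(b_only), "shared": len(shared)}
        gene_lists = annotate_canyons_to_genes(consensus[a], annotation.genes)
        pd.DataFrame(
            {
                "chrom": consensus[a]["chrom"],
                "start": consensus[a]["start"],
                "end": consensus[a]["end"],
                "genes": [",".join(g) for g in gene_lists],
            }
        ).to_csv(out / f"canyon_genes_{a}.tsv", sep="\t", index=False)

    # --- stage 4: promoter differential methylation ------------------------
    promoters = drop_chromosome(promoter_windows(annotation.genes), config.drop_chrom)
    prom_mat = map_to_regions(samples, promoters, groups=groups)
    prom_mat.values.index = promoters["name"].to_numpy()
    prom_mat.features.index = promoters["name"].to_numpy()
    normal = group_names[0]
    tumor = group_names[1] if len(group_names) > 1 else group_names[0]
    pdmr = region_dmr_test(prom_mat, tumor, normal, min_delta=0.0, alpha=config.alpha)
    _write(pdmr, out / "promoter_dmrs.tsv")
    sig = pdmr[pdmr["significant"]]
    counts["promoter_dmrs"] = int(len(sig))
    counts["promoter_dmrs_hyper"] = int((sig["direction"] == "hyper").sum())
    counts["promoter_dmrs_hypo"] = int((sig["direction"] == "hypo").sum())
    results["promoter_dmrs"] = pdmr
    top = top_variable(prom_mat, config.top_variable_fraction)
    _write(top.values, out / "top_variable_promoters.tsv", index=True)

    # --- stage 5: CIMP marker check ----------------------------------------
    cimp_table, concordant = cimp_check(prom_mat, normal, tumor, alpha=config.alpha)
    _write(cimp_table, out / "cimp_check.tsv")
    counts["cimp_no_significant_marker"] = bool(concordant)

    # --- stage 6: race pDMRs (cross-platform) -------------------------------
    if array_matrix is not None:
        wgbs_cohort = wgbs[tumor]
        pdmr_race, audit, diag = race_pdmr_pipeline(
            {sid: samples[sid] for sid in wgbs_cohort},
            array_matrix,
            annotation.probes,
            annotation.genes,
            min_delta=config.race_min_delta,
            alpha=config.alpha,
        )
        _write(pdmr_race, out / "race_pdmrs.tsv")
        counts["race_pdmr_audit"] = audit
        counts["race_contrast_frac_positive"] = round(diag.frac_positive, 6)
        counts["race_contrast_symmetric"] = bool(diag.symmetric)
        results["race_pdmrs"] = pdmr_race

    # --- stage 7: enrichment -----------------------------------------------
    if config.gmt:
        collection = read_gmt(config.gmt)
        universe = list(annotation.genes["gene"])
        if len(group_names) >= 2 and counts.get("unique_canyons"):
            genes_a = sorted({g for gl in gene_lists for g in gl})
            enr = ora_collection(genes_a, collection, universe)
            _write(enr, out / "canyon_enrichment.tsv")
            counts["enriched_sets"] = int((enr["p_adj"] < config.alpha).sum()) if len(enr) else 0

    params = asdict(config)
    params.pop("outdir", None)  # not an analysis parameter; keeps runs comparable
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": _jsonable(params),
        "counts": _jsonable(counts),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["counts"] = counts
    results["manifest"] = manifest
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
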