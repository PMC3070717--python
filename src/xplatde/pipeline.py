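"""End-to-end pipeline: simulate -> preprocess -> harmonize -> DE ->
commonality -> structure -> enrichment -> report.

Every stage writes its outputs as deterministic TSV (no timestamps), so
two runs with the same config and seed are byte-identical.  All
randomness flows from the single configured seed.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import commonality as cm
from . import diffexpr as de
from . import enrichment as en
from . import harmonize as hz
from . import io_formats as io
from . import preprocess as pp
from . import structure as st
from . import synthetic as syn

log = logging.getLogger("xplatde")


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    alpha: float = 0.05
    lam: float = 0.5           # Storey pi0 tuning parameter
    tolerance: int = 1         # group-common marker slack ("all but one")
    min_pathways: int = 2
    kmeans_k: int = 24
    kmeans_restarts: int = 10
    correlation_chromosome: str = "1"
    run_raw_stage: bool = True
    run_structure_stage: bool = True
    run_enrichment_stage: bool = True
    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    sim: syn.SimulationConfig | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise io.ValidationError("alpha must lie in (0, 1)")
        if not (0.0 <= self.lam < 1.0):
            raise io.ValidationError("lambda must lie in [0, 1)")
        if self.tolerance < 0:
            raise io.ValidationError("tolerance must be non-negative")

    def simulation(self) -> syn.SimulationConfig:
        if self.sim is not None:
            return self.sim
        return syn.SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "preprocess" in raw:
            raw["preprocess"] = pp.PreprocessConfig(**raw["preprocess"])
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "platforms" in sim:
                sim["platforms"] = tuple(
                    syn.PlatformSpec(**p) for p in sim["platforms"]
                )
            for key in ("groups", "term_size_range", "chromosome_weights"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            raw["sim"] = syn.SimulationConfig(**sim)
        return cls(**raw)


def _write_report_frames(reports: list[cm.CommonalityReport], path: Path) -> None:
    frames = [r.to_frame() for r in reports]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["rule_id", "gene_id"])
    )
    out.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage, write all outputs, return the key objects."""
    out = Path(config.out_dir)
    for sub in ("sim", "preprocess", "harmonize", "de", "common",
                "structure", "enrich"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    sim = config.simulation()
    results: dict = {"config": config}

    # --- simulate ---------------------------------------------------------
    log.info("stage simulate: %d genes, %d platforms", sim.n_genes_universe,
             len(sim.platforms))
    studies, meta, annotations, truth = syn.generate_multiplatform_study(sim)
    io.write_sample_meta(meta, out / "sim" / "meta.tsv")
    io.write_gene_labels(truth.labels(), out / "sim" / "truth.tsv")
    for study, ann in zip(studies, annotations):
        io.write_expression_tsv(study, out / "sim" / f"expr_{study.platform_id}.tsv")
        io.write_annotation_tsv(ann, out / "sim" / f"annot_{ann.platform_id}.tsv")
    results.update(meta=meta, truth=truth, annotations=annotations)

    # --- raw-spot preprocessing demo (platform 0) -------------------------
    if config.run_raw_stage:
        log.info("stage preprocess: raw spot layer for %s",
                 sim.platforms[0].platform_id)
        raw = syn.generate_codelink_raw(sim)
        study0, flag_summary = pp.preprocess_raw_arrays(
            raw, config.preprocess, sim.platforms[0].platform_id
        )
        normalized0 = pp.global_median_normalize(study0)
        flag_summary.to_csv(out / "preprocess" / "flag_summary.tsv", sep="\t")
        io.write_expression_tsv(
            normalized0, out / "preprocess" / "normalized_raw_platform.tsv"
        )
        with open(out / "preprocess" / "thresholds.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(config.preprocess), fh,
                           sort_keys=True)
        results["flag_summary"] = flag_summary

    # --- per-platform ratios, collapse, harmonize -------------------------
    log.info("stage harmonize")
    ratio_matrices = []
    for study, ann in zip(studies, annotations):
        normalized = pp.global_median_normalize(study)
        ratios = pp.compute_log_ratios(normalized, meta, include_controls=True)
        ratio_matrices.append(pp.collapse_probes(ratios, ann))
    common_genes = hz.build_common_gene_list(annotations)
    harmonized = hz.quantile_cross_normalize(
        ratio_matrices, meta, sim.groups, common_genes=common_genes
    )
    io.write_matrix_tsv(harmonized.to_frame(), out / "harmonize" / "harmonized.tsv",
                        index_label="gene_id")
    pd.Series(common_genes, name="gene_id").to_csv(
        out / "harmonize" / "common_genes.tsv", sep="\t", index=False
    )
    results["harmonized"] = harmonized

    # --- differential expression ------------------------------------------
    log.info("stage de: alpha=%g lambda=%g", config.alpha, config.lam)
    group_calls = de.add_qvalues(
        de.all_groups_ttests(harmonized, alpha=config.alpha), lam=config.lam
    )
    platform_calls = de.add_qvalues(
        de.per_platform_ttests(harmonized, alpha=config.alpha), lam=config.lam
    )
    tumor_ratios = harmonized.tumor_ratio_matrix()
    intra_calls = de.add_qvalues(
        de.intra_experimental_ztest(tumor_ratios, alpha=config.alpha), lam=config.lam
    )
    inter_calls = de.add_qvalues(
        de.inter_experimental_ztest(tumor_ratios, alpha=config.alpha), lam=config.lam
    )
    for name, calls in (
        ("calls_groups", group_calls),
        ("calls_platforms", platform_calls),
        ("calls_intra", intra_calls),
        ("calls_inter", inter_calls),
    ):
        calls.to_csv(out / "de" / f"{name}.tsv", sep="\t", index=False,
                     float_format="%.17g")
    results.update(group_calls=group_calls, platform_calls=platform_calls,
                   intra_calls=intra_calls, inter_calls=inter_calls)

    # --- commonality -------------------------------------------------------
    log.info("stage common")
    up_all, down_all = cm.cross_platform_direction_sets(platform_calls)
    de_all_samples = cm.intersect_de_all_units(intra_calls)
    group_tables = {g: group_calls[group_calls["unit"] == g]
                    for g in group_calls["unit"].unique()}
    marker = cm.group_common_marker(group_tables, tolerance=config.tolerance)
    case_a = cm.combined_case_selection(
        intra_calls, inter_calls, "intra_unchanged_inter_DE", alpha=config.alpha
    )
    case_b = cm.combined_case_selection(
        intra_calls, inter_calls, "inter_unchanged_intra_DE", alpha=config.alpha
    )
    incidence = cm.de_incidence_ranking(intra_calls)
    reports = [up_all, down_all, de_all_samples, marker, case_a, case_b]
    _write_report_frames(reports, out / "common" / "reports.tsv")
    incidence.to_csv(out / "common" / "incidence.tsv", sep="\t", index=False,
                     float_format="%.17g")
    results.update(up_in_all=up_all, down_in_all=down_all,
                   de_in_all_samples=de_all_samples, group_marker=marker,
                   case_a=case_a, case_b=case_b, incidence=incidence)

    common_set = sorted(up_all.gene_ids | down_all.gene_ids)

    # --- structure ---------------------------------------------------------
    universe_annotation, terms = syn.generate_annotation_and_terms(sim)
    if config.run_structure_stage:
        log.info("stage structure")
        frame = harmonized.to_frame()
        dend = st.hierarchical_cluster(frame, axis="samples")
        (out / "structure" / "samples.nwk").write_text(st.to_newick(dend))
        k = min(config.kmeans_k, frame.shape[0])
        km = st.kmeans_cluster(frame, k=k, seed=config.seed,
                               n_restarts=config.kmeans_restarts)
        pd.DataFrame({"gene_id": frame.index, "cluster": km.assignments}).to_csv(
            out / "structure" / "kmeans_assignments.tsv", sep="\t", index=False
        )
        pca_res = st.pca(frame.T)
        pd.DataFrame({"component": np.arange(1, len(pca_res.variance_fractions) + 1),
                      "variance_fraction": pca_res.variance_fractions}).to_csv(
            out / "structure" / "pca_variance.tsv", sep="\t", index=False,
            float_format="%.17g")
        dist = st.chromosome_distribution(common_set, universe_annotation) \
            if common_set else st.chromosome_distribution([], universe_annotation)
        dist.to_csv(out / "structure" / "chrom_distribution.tsv", sep="\t",
                    float_format="%.17g")
        means = st.chromosome_mean_expression(
            tumor_ratios, universe_annotation,
            {"up": set(up_all.gene_ids), "down": set(down_all.gene_ids)},
        )
        means.to_csv(out / "structure" / "chrom_means.tsv", sep="\t",
                     float_format="%.17g")
        corr = st.chromosome_correlation_map(
            tumor_ratios, universe_annotation, config.correlation_chromosome
        )
        io.write_matrix_tsv(corr.matrix, out / "structure" / "corr_map.tsv",
                            index_label="sample_id")
        results.update(dendrogram=dend, kmeans=km, pca=pca_res,
                       chrom_distribution=dist, chrom_means=means, corr_map=corr)

    # --- enrichment --------------------------------------------------------
    if config.run_enrichment_stage and common_set:
        log.info("stage enrich: %d query genes", len(common_set))
        enrich = en.hypergeometric_enrichment(
            common_set, terms, harmonized.gene_ids, lam=config.lam
        )
        enrich.to_csv(out / "enrich" / "enrichment.tsv", sep="\t", index=False,
                      float_format="%.17g")
        results["enrichment"] = enrich

    # --- provenance and summary -------------------------------------------
    provenance = {
        "seed": config.seed,
        "alpha": config.alpha,
        "lambda": config.lam,
        "tolerance": config.tolerance,
        "preprocess": dataclasses.asdict(config.preprocess),
        "simulation": {
            "n_genes_universe": sim.n_genes_universe,
            "platforms": [dataclasses.asdict(p) for p in sim.platforms],
            "n_common_up": sim.n_common_up,
            "n_common_down": sim.n_common_down,
            "effect_common": sim.effect_common,
            "noise_sd": sim.noise_sd,
            "seed": sim.seed,
        },
        "n_common_genes": len(common_genes),
        "stages": {
            "raw": config.run_raw_stage,
            "structure": config.run_structure_stage,
            "enrichment": config.run_enrichment_stage,
        },
    }
    with open(out / "provenance.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    summary = report(out)
    summary.to_csv(out / "report.tsv", sep="\t", index=False,
                   float_format="%.17g")
    results["report"] = summary
    return results


def report(run_dir) -> pd.DataFrame:
    """Join commonality, incidence and chromosome outputs per gene."""
    run_dir = Path(run_dir)
    reports_path = run_dir / "common" / "reports.tsv"
    if not reports_path.exists():
        raise io.ValidationError("missing stage output: common")
    reports = pd.read_csv(reports_path, sep="\t")
    if reports.empty:
        return pd.DataFrame(
            columns=["rule_id", "gene_id", "n_units_de", "fraction", "chromosome"]
        )
    incidence = pd.read_csv(run_dir / "common" / "incidence.tsv", sep="\t")
    out = reports.merge(incidence, on="gene_id", how="left")
    annot_paths = sorted(run_dir.glob("sim/annot_*.tsv"))
    if annot_paths:
        ann = pd.read_csv(annot_paths[0], sep="\t")
        chrom = ann.drop_duplicates("gene_id")[["gene_id", "chromosome"]]
        out = out.merge(chrom, on="gene_id", how="left")
    return out.sort_values(["rule_id", "gene_id"], kind="stable").reset_index(drop=True)
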