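"""End-to-end orchestration: qc -> trajectory -> divergence -> enrichment
-> network -> prioritize, from a single validated configuration.

Every stage writes self-describing TSVs whose header comments record the
package version, the config hash and the seed, so a rerun with the same
config is byte-identical.  A JSON manifest lists input checksums and the
files each stage produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import divergence as dv
from . import enrichment as en
from . import network as nw
from . import prioritize as pr
from . import qc as qcmod
from . import trajectory as tj
from .config import config_hash, validate_config
from .io import (
    ExpressionMatrix,
    hormones_wide,
    read_annotation_table,
    read_expression,
    read_hormones,
    read_sample_table,
    write_tsv,
)
from .synthetic import TruthSpec, generate_dataset, write_dataset

log = logging.getLogger("budtraj")

STAGES = ("qc", "trajectory", "divergence", "enrichment", "network", "prioritize")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run (also written to the run dir)."""

    config: dict[str, Any]
    outdir: Path
    qc_report: Any = None
    expressed: ExpressionMatrix | None = None
    assignment: tj.ClusterAssignment | None = None
    trajectories: tj.TrajectoryMatrix | None = None
    divergence_table: pd.DataFrame | None = None
    cluster_divergence: pd.DataFrame | None = None
    flagged_clusters: set = field(default_factory=set)
    candidates: pd.Index | None = None
    candidate_counts: pd.Series | None = None
    enrichment: pd.DataFrame | None = None
    modules: pd.Series | None = None
    eigengenes: pd.DataFrame | None = None
    trait_corr: pd.DataFrame | None = None
    trait_pval: pd.DataFrame | None = None
    trait_fits: dict | None = None
    consensus: Any = None
    centrality: pd.DataFrame | None = None
    priority: pd.DataFrame | None = None
    priority_top: pd.DataFrame | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(cfg: dict[str, Any], outdir: Path):
    """Read the four inputs, or simulate them when the config says so."""
    if cfg["simulate"]["enabled"]:
        spec = TruthSpec(
            n_genes=cfg["simulate"]["n_genes"],
            noise_sd=cfg["simulate"]["noise_sd"],
            baseline_sd=cfg["simulate"]["baseline_sd"],
            reps=cfg["simulate"]["reps"],
            seed=cfg["seed"],
        )
        ds = generate_dataset(spec)
        write_dataset(ds, outdir / "simulated_inputs")
        return ds.expression, ds.hormones, ds.annotations
    paths = cfg["inputs"]
    design = read_sample_table(paths["samples"])
    expr = read_expression(paths["expression"], design)
    horm = read_hormones(paths["hormones"], design)
    ann = read_annotation_table(paths["annotations"], paths.get("classes"))
    return expr, horm, ann


def run_pipeline(config: dict[str, Any] | None, outdir: str | Path,
                 through: str = "prioritize") -> PipelineResult:
    """Execute the pipeline up to stage ``through`` and write outputs.

    Stage order: qc, trajectory, divergence, enrichment, network,
    prioritize.  Any stage failure aborts with the stage name attached.
    """
    cfg = validate_config(config or {})
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"budtraj {__version__}",
        f"config_hash {config_hash(cfg)}",
        f"seed {cfg['seed']}",
    ]
    manifest: dict[str, Any] = {"version": __version__,
                                "config_hash": config_hash(cfg),
                                "seed": cfg["seed"], "inputs": {}, "outputs": []}

    def emit(df: pd.DataFrame, name: str, index: bool = False,
             doc: str = "") -> None:
        path = outdir / name
        comments = header + ([doc] if doc else [])
        write_tsv(df, path, comments, index=index)
        manifest["outputs"].append(name)

    with open(outdir / "config_normalized.json", "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)

    expr, horm, ann = load_inputs(cfg, outdir)
    if not cfg["simulate"]["enabled"]:
        for key, p in cfg["inputs"].items():
            if p:
                manifest["inputs"][key] = _sha256(Path(p))

    result = PipelineResult(config=cfg, outdir=outdir)
    last = STAGES.index(through)

    # ---------------------------------------------------------------- qc
    try:
        report, corr, scores = qcmod.qc_report(
            expr, min_tpm=cfg["qc"]["min_tpm"],
            min_libraries=cfg["qc"]["min_libraries"],
            n_top_genes=cfg["qc"]["n_top_genes"])
        expressed = qcmod.filter_expressed(
            expr, cfg["qc"]["min_tpm"], cfg["qc"]["min_libraries"])
        logx = qcmod.log2p1(expressed.values)
        result.qc_report, result.expressed = report, expressed
        rep_df = pd.DataFrame([{
            "n_genes_total": report.n_genes_total,
            "n_genes_expressed": report.n_genes_expressed,
            "within_group_corr_min": report.within_group_correlation_range[0],
            "within_group_corr_max": report.within_group_correlation_range[1],
            **{f"pc{i + 1}_var_frac": f
               for i, f in enumerate(report.pc_variance_fractions[:5])},
        }])
        emit(rep_df, "qc_report.tsv",
             doc="gene counts, replicate concordance, PC variance fractions")
        emit(corr.rename_axis("sample"), "sample_correlations.tsv", index=True,
             doc="sample x sample Pearson correlation of log2(TPM+1)")
        emit(scores.rename_axis("sample"), "pca_scores.tsv", index=True,
             doc="per-sample PCA scores on the most variable genes")
    except Exception as exc:                       # pragma: no cover - passthrough
        raise StageError("qc", exc) from exc
    if last == 0:
        return result

    # -------------------------------------------------------- trajectory
    try:
        means_traj = qcmod.replicate_means(expressed.values, expressed.design,
                                           scale=cfg["trajectory"]["scale"])
        traj = tj.zscore_trajectories(means_traj)
        assignment = tj.cluster_kmeans(traj, k=cfg["trajectory"]["k"],
                                       seed=cfg["seed"],
                                       n_restarts=cfg["trajectory"]["n_restarts"])
        profiles = tj.cluster_group_profiles(assignment, traj, expressed.design)
        result.trajectories, result.assignment = traj, assignment
        clusters_df = pd.DataFrame({
            "cluster": assignment.labels.reindex(traj.z.index),
            "valid": traj.valid,
        }).rename_axis("gene")
        emit(clusters_df, "clusters.tsv", index=True,
             doc="trajectory module per gene (C1..Ck by decreasing size)")
        cent = assignment.centroids.copy()
        cent.columns = [f"{c}_{s}" for c, s in cent.columns]
        emit(cent.rename_axis("cluster"), "centroids.tsv", index=True)
        emit(profiles.reset_index(), "group_profiles.tsv",
             doc="cluster-average z trajectories per CR group")
    except Exception as exc:
        raise StageError("trajectory", exc) from exc
    if last == 1:
        return result

    # -------------------------------------------------------- divergence
    try:
        log_means = qcmod.replicate_means(expressed.values, expressed.design,
                                          scale="log")
        groups = dv.group_stage_means(log_means, expressed.design)
        d = dv.stage_group_difference(log_means, expressed.design)
        disc = dv.discordance_flag(d, eps=cfg["divergence"]["eps"])
        trend, conc_count, conc_pass = dv.cultivar_concordance(
            log_means, eps=cfg["divergence"]["eps"],
            k_of_n=cfg["divergence"]["concordance_k"])
        abund = dv.abundance_gate(expressed.values,
                                  cfg["divergence"]["abundance_min_mean"],
                                  cfg["divergence"]["abundance_min_max"])
        classes = ann.class_of(expressed.genes)
        cluster_div = dv.module_stage_divergence(d, assignment)
        flagged, flag_table = tj.flag_cr_divergent_clusters(
            assignment, disc, cfg["trajectory"]["tau_discordant"])
        candidates, counts = dv.select_candidates(
            assignment, flagged, disc, conc_pass, abund, classes)
        gene_table = dv.build_divergence_table(
            d, groups, disc, trend, conc_count, conc_pass, abund, classes,
            assignment.labels)
        result.divergence_table = gene_table
        result.cluster_divergence = cluster_div
        result.flagged_clusters = flagged
        result.candidates, result.candidate_counts = candidates, counts
        emit(gene_table.rename_axis("gene"), "divergence_genes.tsv", index=True,
             doc="per-gene High-Low stage differences, discordance, filters")
        emit(cluster_div.join(flag_table).rename_axis("cluster"),
             "divergence_clusters.tsv", index=True,
             doc="cluster x stage mean |High-Low| divergence and flags")
        cand_df = gene_table.loc[candidates, ["cluster", "class"]]
        emit(cand_df.rename_axis("gene"), "candidates.tsv", index=True,
             doc="genes passing divergence, concordance, abundance, class")
    except Exception as exc:
        raise StageError("divergence", exc) from exc
    if last == 2:
        return result

    # -------------------------------------------------------- enrichment
    try:
        universe = set(expressed.genes)
        enr = en.enrich_clusters(assignment.labels, ann, universe,
                                 alpha=cfg["enrichment"]["alpha"])
        result.enrichment = enr
        for layer, sub in enr.groupby("layer"):
            emit(sub.drop(columns="layer"), f"enrichment_{layer}.tsv",
                 doc="hypergeometric over-representation, BH FDR within layer")
    except Exception as exc:
        raise StageError("enrichment", exc) from exc
    if last == 3:
        return result

    # ----------------------------------------------------------- network
    try:
        net_cfg = cfg["network"]
        cand = list(candidates)
        resid = nw.residualize_by_stage(logx.loc[cand], expressed.design)
        pooled = nw.correlation_network(resid, min_abs_r=net_cfg["min_abs_r"])
        # module layer: residualize within cultivar as well, so modules and
        # eigengenes reflect shared regulatory covariation rather than
        # genotype baselines (which a stage-only residual retains)
        resid_wc = nw.residualize_by_stage(logx.loc[cand], expressed.design,
                                           within_cultivar=True)
        corr_cand = nw.correlation_matrix(resid_wc)
        adj = nw.adjacency_from_corr(corr_cand, beta=net_cfg["beta"])
        tom = nw.tom_similarity(adj)
        modules = nw.detect_modules(tom, net_cfg["min_module_size"],
                                    net_cfg["cut_height"])
        mes, explained = nw.module_eigengenes(resid_wc, modules)
        traits = nw.trait_frame(expressed.design,
                                hormones_wide(horm, expressed.design))
        if len(mes.columns):
            tcorr, tpval, tfits = nw.module_trait_association(mes, traits)
        else:
            tcorr = tpval = pd.DataFrame()
            tfits = {}
        per_cult = nw.per_cultivar_correlations(logx.loc[cand], expressed.design)
        consensus = nw.consensus_network(per_cult, k_of_n=net_cfg["consensus_k"],
                                         min_abs_r=net_cfg["consensus_min_abs_r"])
        for node in consensus.nodes:
            consensus.nodes[node]["module"] = str(modules.get(node, nw.UNASSIGNED))
        centrality = nw.node_centrality(consensus)
        result.modules, result.eigengenes = modules, mes
        result.trait_corr, result.trait_pval, result.trait_fits = tcorr, tpval, tfits
        result.consensus, result.centrality = consensus, centrality
        emit(nw.edges_frame(consensus), "edges.tsv",
             doc="consensus edges: signed min |r| weight, support count, per-cultivar r")
        mod_df = pd.DataFrame({"module": modules,
                               "pooled_degree": pd.Series(
                                   dict(pooled.degree())).reindex(modules.index),
                               "consensus_degree": centrality["degree"].reindex(
                                   modules.index).fillna(0).astype(int)})
        emit(mod_df.rename_axis("gene"), "modules.tsv", index=True,
             doc="WGCNA-style module colours and degrees of candidate genes")
        if len(mes.columns):
            emit(mes.rename_axis("sample_id"), "eigengenes.tsv", index=True,
                 doc="module eigengenes (unit variance, sign-aligned)")
            mt = tcorr.copy()
            mt.columns = [f"r_{c}" for c in mt.columns]
            for c in tpval.columns:
                mt[f"p_{c}"] = tpval[c]
            emit(mt.rename_axis("module"), "module_trait.tsv", index=True,
                 doc="eigengene-trait Pearson r and two-sided p")
        nw.write_graphml(consensus, outdir / "consensus.graphml")
        nw.write_sif(consensus, outdir / "consensus.sif")
        manifest["outputs"] += ["consensus.graphml", "consensus.sif"]
    except Exception as exc:
        raise StageError("network", exc) from exc
    if last == 4:
        return result

    # -------------------------------------------------------- prioritize
    try:
        eligible = assignment.labels.index[
            assignment.labels.isin(result.flagged_clusters)]
        comp = pr.evidence_components(
            eligible, d, centrality,
            conc_count, len(set(expressed.design["cultivar"])),
            abund, assignment.labels, classes)
        scores = pr.priority_score(comp, cfg["prioritize"]["weights"])
        full, top = pr.rank_candidates(comp, scores, cfg["prioritize"]["top_n"])
        profiles_top = pr.stage_profiles_report(expressed.values,
                                                expressed.design, top.index)
        result.priority, result.priority_top = full, top
        wdoc = "weights " + json.dumps(cfg["prioritize"]["weights"],
                                       sort_keys=True)
        emit(full.rename_axis("gene"), "priority_full.tsv", index=True, doc=wdoc)
        emit(top.rename_axis("gene"), "priority_top.tsv", index=True, doc=wdoc)
        emit(profiles_top, "stage_profiles_top.tsv",
             doc="Low/High stage means +/- s.e.m., log2(TPM+1)")
    except Exception as exc:
        raise StageError("prioritize", exc) from exc

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
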