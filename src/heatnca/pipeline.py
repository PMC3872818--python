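"""End-to-end pipeline: differential expression -> signed network -> NCA ->
activity report, with a config object, run logging and reproducible output.

The stages chain exactly as in the study's workflow: per-ecotype t-tests at
``alpha`` pick the differentially expressed genes; the TF layer is the
DE TFs (optionally intersected with a curated heat-responsive list); the
signed bipartite network thresholds Pearson correlations of per-ecotype
log2 fold-change profiles at ``corr_threshold``; the network (reduced to an
identifiable core) constrains the NCA fit of TF activities, which are then
classified as ecotype-specific or multi-responsive.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import de as de_mod
from . import io as io_mod
from . import network as net_mod
from . import nca as nca_mod
from . import reporting as rep_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    alpha: float = 0.01            # DE significance cutoff (raw p)
    corr_threshold: float = 0.8    # |r| cutoff for network edges
    corr_axis: str = "foldchange"  # 'foldchange' (per-ecotype log2fc) or 'samples'
    tol: float = 1e-6
    max_iter: int = 500
    ridge: float = 0.0
    threshold_z: float = 2.0
    n_boot: int = 200
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must be in (0, 1]")
        if self.corr_axis not in ("foldchange", "samples"):
            raise ValueError("corr_axis must be 'foldchange' or 'samples'")
        if self.tol <= 0 or self.max_iter <= 0:
            raise ValueError("tol and max_iter must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be nonnegative")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class StageError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def run_pipeline(expr: de_mod.ExpressionMatrix, annot: de_mod.AnnotationTable,
                 config: PipelineConfig, outdir: str | Path,
                 curated_tfs: set[str] | None = None) -> dict:
    """Run de -> network -> nca -> report and write artifacts to ``outdir``.

    Returns a dict of in-memory results (records, summary, network, model,
    activity profile).  Reruns with the same inputs and config are
    bit-identical for the deterministic stages; the only randomness (NCA
    initialization without a signed prior, bootstrap) is governed by
    ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("heatnca")
    root.addHandler(handler)
    try:
        config.to_yaml(outdir / "config.yaml")
        logger.info("pipeline start; seed=%d alpha=%g corr_threshold=%g",
                    config.seed, config.alpha, config.corr_threshold)
        results = _run_stages(expr, annot, config, outdir, curated_tfs)
        logger.info("pipeline done")
        return results
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(expr, annot, config, outdir, curated_tfs):
    records = _de_stage(expr, config, outdir)
    network = _network_stage(expr, records, annot, config, outdir, curated_tfs)
    model, fc = _nca_stage(expr, network, config, outdir)
    profile = _report_stage(model, network, fc, config, outdir)
    return {"records": records, "network": network, "model": model,
            "profile": profile}


@_stage("de")
def _de_stage(expr, config, outdir):
    records = de_mod.de_records_all_ecotypes(expr, config.alpha,
                                             with_interaction=True)
    summary, membership = de_mod.assemble_union(records)
    io_mod.write_table(records, outdir / "de_records.tsv",
                       "per-gene, per-ecotype differential expression")
    io_mod.write_table(summary.per_ecotype.reset_index(),
                       outdir / "de_summary.tsv",
                       f"unified={summary.unified_count} "
                       f"unique={summary.unique_overall_count}")
    logger.info("de: unified %d, unique %d", summary.unified_count,
                summary.unique_overall_count)
    return records


@_stage("network")
def _network_stage(expr, records, annot, config, outdir, curated_tfs):
    sig = records[records["significant"]]
    de_genes = set(sig["gene_id"])
    de_tfs = {g for g in de_genes if "TF" in annot.tags_for(g)}
    if curated_tfs is not None:
        tf_ids = net_mod.intersect_curated(de_tfs, curated_tfs)
    else:
        tf_ids = sorted(de_tfs)
    if not tf_ids:
        raise ValueError("no differentially expressed TFs to anchor the network")
    targets = sorted(de_genes - set(tf_ids))
    fc = de_mod.fold_change_matrix(expr)
    if config.corr_axis == "foldchange":
        profiles = fc
    else:
        profiles = __import__("pandas").DataFrame(
            expr.values, index=expr.gene_index(), columns=expr.sample_ids)
    corr = net_mod.correlation_profiles(profiles.loc[tf_ids].to_numpy(),
                                        profiles.loc[targets].to_numpy())
    network = net_mod.build_signed_network(corr, config.corr_threshold,
                                           tf_ids, targets)
    io_mod.write_edge_list(network, outdir / "network_edges.tsv")
    io_mod.write_sif(network, outdir / "network.sif")
    io_mod.write_table(net_mod.degree_table(network), outdir / "degree_table.tsv")
    logger.info("network: %d TFs, %d targets, %d edges", len(network.tfs),
                len(network.targets), network.n_edges)
    return network


@_stage("nca")
def _nca_stage(expr, network, config, outdir):
    fc = de_mod.fold_change_matrix(expr)
    pattern = network.to_pattern()
    reduced, removed = nca_mod.reduce_to_identifiable(pattern)
    if removed:
        logger.warning("nca: removed %d non-identifiable TFs: %s", len(removed),
                       [network.tfs[i] for i in removed])
    kept_tfs = [t for i, t in enumerate(network.tfs) if i not in set(removed)]
    e = fc.loc[network.targets].to_numpy()
    model = nca_mod.fit_nca(e, reduced, tol=config.tol,
                            max_iter=config.max_iter, ridge=config.ridge,
                            seed=config.seed)
    io_mod.write_matrix(model.p_hat, kept_tfs, list(fc.columns),
                        outdir / "tfa.tsv", "inferred TF activities (TF x ecotype)")
    io_mod.write_matrix(model.a_hat, network.targets, kept_tfs,
                        outdir / "control_strengths.tsv",
                        "fitted control strengths (target x TF)")
    meta = {
        "tol": config.tol, "max_iter": config.max_iter,
        "ridge_applied": model.ridge, "iterations": model.iterations,
        "converged": bool(model.converged), "seed": config.seed,
        "final_residual": model.residual_trace[-1] if model.residual_trace else 0.0,
    }
    with open(outdir / "nca_run.txt", "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}\t{v}\n")
    logger.info("nca: %d iterations, converged=%s, ridge=%g",
                model.iterations, model.converged, model.ridge)
    model.tf_ids = kept_tfs  # type: ignore[attr-defined]
    return model, fc


@_stage("report")
def _report_stage(model, network, fc, config, outdir):
    tf_ids = getattr(model, "tf_ids", network.tfs)
    profile = rep_mod.classify_responsive(model.p_hat, tf_ids,
                                          list(fc.columns), config.threshold_z)
    io_mod.write_table(profile.to_frame(), outdir / "tf_activity_calls.tsv",
                       "ecotype-specific vs multi-responsive TF classification")
    if len(tf_ids) >= 2:
        clust = rep_mod.hierarchical_cluster(model.p_hat)
        newick = rep_mod.linkage_to_newick(
            clust.linkage, [tf_ids[i] for i in clust.kept])
        (outdir / "tfa_tree.nwk").write_text(newick + "\n")
    logger.info("report: %d unique, %d multi, %d none",
                profile.category.count("unique"),
                profile.category.count("multi"),
                profile.category.count("none"))
    return profile
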