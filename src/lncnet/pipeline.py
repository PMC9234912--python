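"""End-to-end orchestration of the inference cascade.

Stage order: joint transcript preprocessing (log2 → optional background filter
→ quantile normalization → batch adjustment → layer split by ID prefix) and
OTU preprocessing (log2 of normalized counts) → per-layer differential tests
(BH FDR ≤ α; fold-change gate on the mRNA layer only) → overrepresentation on
the gated mRNA list → curated category selection → gene pooling → Z-scoring of
significant features → lncRNA:mRNA network (|r| > 0.95) → intersection of the
pooled genes with the disease gene list → network restriction to the overlap →
median-|r| importance on both sides → lncRNA:OTU co-abundance network
(|r| > 0.5, p < 0.05) → per-layer and hub/OTU PCA.  Every stage logs its
counts; the funnel of shrinking feature sets is reported as JSON.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .diffexpr import (apply_de_filters, infer_layer_from_prefix,
                       moderated_t_test, two_sample_t)
from .enrichment import (intersect_gene_lists, overrepresentation_test,
                         pool_unique_genes, select_categories)
from .network import (BipartiteCorrelationNetwork, CorrelationMatrix,
                      build_network, cross_layer_correlation,
                      median_importance, otu_coabundance,
                      otu_sign_consistency, restrict_network)
from .ordination import group_separation, pca
from .preprocess import (BackgroundModel, batch_adjust, filter_above_background,
                         log2_transform, quantile_normalize, zscore_rows)
from .simulate import CohortBundle, SyntheticConfig, generate_cohort, load_fixture
from .types import Layer, OmicsMatrix, Scale

__all__ = ["PipelineConfig", "PipelineError", "ResultBundle",
           "run_all", "report_funnel"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A required stage produced an empty set; carries the stage name."""


@dataclass
class PipelineConfig:
    """All thresholds and inputs of one cascade run.

    Exactly one of ``fixture_dir`` (a directory written by
    :func:`lncnet.simulate.write_fixture`) or ``synthetic`` (an inline
    :class:`SyntheticConfig`) must be set.
    """

    fixture_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    # preprocessing
    expr_pseudocount: float = 0.0
    otu_pseudocount: float = 1.0
    min_fraction: float = 0.5
    neg_control_ids: tuple[str, ...] = ()
    batch_factors: tuple[str, ...] | None = None   # None = all metadata factors
    # differential testing
    alpha: float = 0.05
    fc_log2: float = 0.58
    # enrichment curation
    top_n: int = 15
    keywords: tuple[str, ...] = ("bacterium", "microb")
    explicit_sets: tuple[str, ...] | None = None
    # networks
    rmin_lnc_mrna: float = 0.95
    rmin_lnc_otu: float = 0.5
    p_max: float = 0.05
    mode: str = "absolute"
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.fixture_dir is None) == (self.synthetic is None):
            raise ValueError("set exactly one of fixture_dir or synthetic")
        for name in ("rmin_lnc_mrna", "rmin_lnc_otu"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class ResultBundle:
    cohort: CohortBundle
    de_mrna: pd.DataFrame
    de_lncrna: pd.DataFrame
    de_otu: pd.DataFrame
    enrichment: pd.DataFrame
    selected_sets: list
    pooled_genes: list
    disease_overlap: list
    net_lnc_mrna: BipartiteCorrelationNetwork
    net_refined: BipartiteCorrelationNetwork
    net_lnc_otu: BipartiteCorrelationNetwork
    otu_signs: pd.DataFrame
    importance_lncrna: pd.DataFrame
    importance_mrna: pd.DataFrame
    correlation: CorrelationMatrix
    pca_reports: dict                 # name -> {"variance_fraction", "separation"}
    funnel: dict
    config: PipelineConfig


def _split_matrix(m: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    mrna_ids, lnc_ids, unknown = [], [], []
    for fid in m.feature_ids:
        lay = infer_layer_from_prefix(fid)
        if lay == Layer.MRNA:
            mrna_ids.append(fid)
        elif lay == Layer.LNCRNA:
            lnc_ids.append(fid)
        else:
            unknown.append(fid)
    if unknown:
        raise PipelineError(f"layer split: unannotated features {unknown[:5]}")
    return (OmicsMatrix(m.data.loc[mrna_ids], Layer.MRNA, m.scale),
            OmicsMatrix(m.data.loc[lnc_ids], Layer.LNCRNA, m.scale))


def _pca_report(m: OmicsMatrix, meta) -> dict:
    res = pca(m, n_components=2)
    sep = group_separation(res, meta.aligned_to(m))
    return {
        "n_features": m.n_features,
        "variance_fraction_pc1": float(res.variance_fraction[0]),
        "variance_fraction_pc1_pc2": float(res.variance_fraction[:2].sum()),
        "separation": sep["separation"],
        "scores": res.scores,
    }


def run_all(config: PipelineConfig) -> ResultBundle:
    """Execute the full cascade and return every intermediate product."""
    t0 = time.time()
    if config.fixture_dir is not None:
        cohort = load_fixture(config.fixture_dir)
    else:
        cohort = generate_cohort(config.synthetic)
    meta = cohort.metadata

    # --- joint transcript preprocessing ----------------------------------
    combined = OmicsMatrix(pd.concat([cohort.mrna.data, cohort.lncrna.data]),
                           Layer.TRANSCRIPT, Scale.RAW)
    expr = log2_transform(combined, config.expr_pseudocount)
    if config.neg_control_ids:
        bg = BackgroundModel.from_negative_controls(expr, config.neg_control_ids)
        expr = OmicsMatrix(
            expr.data.drop(index=list(config.neg_control_ids)),
            expr.layer, expr.scale)
        expr = filter_above_background(expr, bg, config.min_fraction)
        log.info("background filter retained %d features", expr.n_features)
    else:
        log.info("no negative controls configured; background filter skipped")
    expr = quantile_normalize(expr)
    factors = config.batch_factors
    if factors is None:
        factors = meta.batch_cols
    for factor in factors:
        expr = batch_adjust(expr, meta, factor, preserve="group")
        log.info("batch factor %r adjusted", factor)
    mrna_log2, lnc_log2 = _split_matrix(expr)

    otu_log2 = log2_transform(cohort.otu, config.otu_pseudocount)

    # --- differential testing --------------------------------------------
    de_mrna = apply_de_filters(moderated_t_test(mrna_log2, meta, config.alpha),
                               config.alpha, config.fc_log2, use_fc=True)
    de_lnc = apply_de_filters(moderated_t_test(lnc_log2, meta, config.alpha),
                              config.alpha, config.fc_log2, use_fc=False)
    de_otu = apply_de_filters(two_sample_t(otu_log2, meta, config.alpha),
                              config.alpha, use_fc=False)

    sig_mrna = de_mrna.index[de_mrna["significant"]].tolist()
    gated = de_mrna.index[de_mrna["significant"] & de_mrna["passes_fc"]].tolist()
    sig_lnc = de_lnc.index[de_lnc["significant"]].tolist()
    sig_otu = de_otu.index[de_otu["significant"]].tolist()
    for stage, items in (("differential mRNA", sig_mrna),
                         ("fold-change-gated mRNA", gated),
                         ("differential lncRNA", sig_lnc),
                         ("differential OTU", sig_otu)):
        if not items:
            raise PipelineError(f"stage {stage!r} produced an empty set")

    # --- enrichment + pooling --------------------------------------------
    universe = mrna_log2.feature_ids
    enr = overrepresentation_test(gated, cohort.gene_sets, universe)
    selected = select_categories(enr, config.top_n, config.keywords,
                                 config.explicit_sets)
    if not selected:
        raise PipelineError("stage 'category selection' produced an empty set")
    pooled = pool_unique_genes(cohort.gene_sets, selected, gated)
    if not pooled:
        raise PipelineError("stage 'gene pooling' produced an empty set")

    # --- Z-scoring + lncRNA:mRNA network ---------------------------------
    lnc_sig_z = zscore_rows(lnc_log2.subset_features(sig_lnc))
    mrna_pool_z = zscore_rows(mrna_log2.subset_features(pooled))
    otu_sig_z = zscore_rows(otu_log2.subset_features(sig_otu))

    corr = cross_layer_correlation(lnc_sig_z, mrna_pool_z)
    net54 = build_network(corr, config.rmin_lnc_mrna, config.p_max, config.mode)
    if net54.n_edges == 0:
        raise PipelineError("stage 'lncRNA:mRNA network' produced an empty set")

    overlap = intersect_gene_lists(pooled, cohort.disease_genes)
    if not overlap:
        raise PipelineError("stage 'disease-gene intersection' produced an empty set")
    net_ref = restrict_network(net54, overlap)
    if net_ref.n_edges == 0:
        raise PipelineError("stage 'refined network' produced an empty set")

    corr_ref = corr.restrict(net_ref.side_a, net_ref.side_b)
    imp_lnc = median_importance(corr_ref, axis="a")
    imp_mrna = median_importance(corr_ref, axis="b")
    # direction of change from the per-feature differential effect
    imp_lnc["direction"] = np.sign(
        de_lnc.loc[imp_lnc["node_id"], "log2_fc"].to_numpy()).astype(int)
    imp_mrna["direction"] = np.sign(
        de_mrna.loc[imp_mrna["node_id"], "log2_fc"].to_numpy()).astype(int)

    # --- lncRNA:OTU co-abundance network ---------------------------------
    lnc_hub_z = lnc_sig_z.subset_features(net_ref.side_a)
    net_otu = otu_coabundance(lnc_hub_z, otu_sig_z,
                              config.rmin_lnc_otu, config.p_max)
    signs = otu_sign_consistency(net_otu)

    # --- ordination --------------------------------------------------------
    mrna_sig_z = zscore_rows(mrna_log2.subset_features(sig_mrna))
    pca_reports = {
        "mrna_significant": _pca_report(mrna_sig_z, meta),
        "lncrna_significant": _pca_report(lnc_sig_z, meta),
        "otu_significant": _pca_report(otu_sig_z, meta),
    }
    if net_otu.side_a:
        pca_reports["lncrna_hub"] = _pca_report(
            lnc_sig_z.subset_features(net_otu.side_a), meta)
    if net_otu.side_b:
        pca_reports["otu_coupled"] = _pca_report(
            otu_sig_z.subset_features(net_otu.side_b), meta)

    funnel = {
        "n_samples": combined.n_samples,
        "transcript_features": combined.n_features,
        "de_mrna": len(sig_mrna),
        "de_lncrna": len(sig_lnc),
        "de_otu": len(sig_otu),
        "fc_gated_mrna": len(gated),
        "selected_categories": len(selected),
        "pooled_genes": len(pooled),
        "network_lncrna": len(net54.side_a),
        "network_mrna": len(net54.side_b),
        "disease_overlap": len(overlap),
        "refined_lncrna": len(net_ref.side_a),
        "refined_mrna": len(net_ref.side_b),
        "coabundance_lncrna": len(net_otu.side_a),
        "coabundance_otu": len(net_otu.side_b),
    }
    log.info("funnel: %s (%.2fs)", funnel, time.time() - t0)

    bundle = ResultBundle(
        cohort=cohort, de_mrna=de_mrna, de_lncrna=de_lnc, de_otu=de_otu,
        enrichment=enr, selected_sets=list(selected), pooled_genes=pooled,
        disease_overlap=overlap, net_lnc_mrna=net54, net_refined=net_ref,
        net_lnc_otu=net_otu, otu_signs=signs,
        importance_lncrna=imp_lnc, importance_mrna=imp_mrna,
        correlation=corr, pca_reports=pca_reports, funnel=funnel,
        config=config)
    if config.out_dir is not None:
        write_outputs(bundle, config.out_dir)
    return bundle


def report_funnel(bundle: ResultBundle) -> dict:
    """Per-stage counts with thresholds; the JSON twin of the run log.

    Along the lncRNA funnel the counts are monotonically non-increasing:
    differential → network → disease-restricted → OTU-coupled.
    """
    cfg = bundle.config
    return {
        "thresholds": {
            "alpha": cfg.alpha,
            "fc_log2": cfg.fc_log2,
            "rmin_lnc_mrna": cfg.rmin_lnc_mrna,
            "rmin_lnc_otu": cfg.rmin_lnc_otu,
            "p_max": cfg.p_max,
            "mode": cfg.mode,
        },
        "counts": dict(bundle.funnel),
        "lncrna_funnel": [
            bundle.funnel["de_lncrna"],
            bundle.funnel["network_lncrna"],
            bundle.funnel["refined_lncrna"],
            bundle.funnel["coabundance_lncrna"],
        ],
        "mrna_funnel": [
            bundle.funnel["de_mrna"],
            bundle.funnel["fc_gated_mrna"],
            bundle.funnel["pooled_genes"],
            bundle.funnel["disease_overlap"],
        ],
    }


def write_outputs(bundle: ResultBundle, out_dir) -> dict:
    """Write all tables + a run manifest with output hashes; returns manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def _table(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.12g")
        files[name] = lio.file_sha256(path)

    _table(bundle.de_mrna, "de_mrna.tsv")
    _table(bundle.de_lncrna, "de_lncrna.tsv")
    _table(bundle.de_otu, "de_otu.tsv")
    _table(bundle.enrichment, "enrichment.tsv", index=False)
    for net, name in ((bundle.net_lnc_mrna, "net_lnc_mrna.tsv"),
                      (bundle.net_refined, "net_refined.tsv"),
                      (bundle.net_lnc_otu, "net_lnc_otu.tsv")):
        lio.write_network(net, out / name)
        files[name] = lio.file_sha256(out / name)
    _table(bundle.importance_lncrna, "importance_lncrna.tsv", index=False)
    _table(bundle.importance_mrna, "importance_mrna.tsv", index=False)
    _table(bundle.otu_signs, "otu_signs.tsv", index=False)
    lio.write_gene_list(bundle.pooled_genes, out / "pooled_genes.txt")
    files["pooled_genes.txt"] = lio.file_sha256(out / "pooled_genes.txt")
    lio.write_gene_list(bundle.disease_overlap, out / "disease_overlap.txt")
    files["disease_overlap.txt"] = lio.file_sha256(out / "disease_overlap.txt")

    pca_json = {name: {k: v for k, v in rep.items() if k != "scores"}
                for name, rep in bundle.pca_reports.items()}
    lio.write_json(pca_json, out / "pca_reports.json")
    files["pca_reports.json"] = lio.file_sha256(out / "pca_reports.json")
    lio.write_json(report_funnel(bundle), out / "funnel.json")
    files["funnel.json"] = lio.file_sha256(out / "funnel.json")

    cfg = asdict(bundle.config)
    if cfg.get("synthetic") is not None:
        cfg["synthetic"] = asdict(bundle.config.synthetic)
    manifest = {
        "parameters": cfg,
        "seed": bundle.config.seed,
        "outputs": files,
    }
    lio.write_json(manifest, out / "run_manifest.json")
    return manifest
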