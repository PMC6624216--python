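"""End-to-end orchestration of the five-step SFCC framework.

Steps: (1) preprocess — log2 transform and informative-gene filter;
(2) split cells into anchors and the rest; (3) build the feature space
from the anchors and project everything into it; (4) cluster the
anchors; (5) kNN-classify the rest. With ``feature="identity"`` the
feature space is the raw expression space and the pipeline reduces to
the plain subsampling-clustering-classification (SCC) baseline; with
``feature="spearman"`` it is SSCC.

Also implements the repeated-subsampling evaluation protocol: paired
runs at two rates, scored by the NMI between their full-cohort
labelings and the Pearson correlation of their per-cell silhouette
vectors, averaged over seeded repeats.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import __version__
from .classify import knn_classify
from .cluster import run_backend
from .datamodel import ExpressionMatrix, LabelVector, ValidationError
from .featurize import build_features
from .io import read_labels, read_matrix, write_labels
from .metrics import (adjusted_rand, contingency, fraction_improved,
                      median_silhouette, nmi, pearson_correlation, rand_index,
                      silhouette)
from .preprocess import GeneFilterSpec, filter_informative_genes, log2_transform
from .split import subsample

__all__ = ["RunConfig", "RunReport", "run_sfcc_matrix", "run_sfcc",
           "evaluate_consistency"]

log = logging.getLogger("sscclust")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; all preconditions checkable upfront."""

    input_path: str | None = None
    input_format: str = "mtx_triplet"
    scale_tag: str = "counts"
    truth_path: str | None = None
    feature: str = "spearman"
    backend: str = "kmeans"
    k: int | None = None
    rate: float = 0.1
    knn_k: int = 5
    gene_filter: GeneFilterSpec = field(default_factory=GeneFilterSpec)
    apply_gene_filter: bool = True
    pseudocount: float = 1.0
    seed: int = 0
    n_repeats: int = 10
    out_prefix: str | None = None
    cluster_params: dict = field(default_factory=dict)


@dataclass
class RunReport:
    """Labels plus provenance and (optionally) evaluation metrics."""

    labels: LabelVector
    cell_ids: list[str]
    anchor_indices: np.ndarray
    config: dict
    timings: dict
    metrics: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "version": __version__,
            "seed": self.seed,
            "config": self.config,
            "timings": self.timings,
            "metrics": self.metrics,
            "n_cells": len(self.labels),
            "n_anchors": int(self.anchor_indices.size),
            "n_clusters": int(self.labels.n_categories()),
        }, indent=2, sort_keys=True)


def _preprocess(expr: ExpressionMatrix, config: RunConfig) -> ExpressionMatrix:
    if expr.scale_tag != "log2":
        expr = log2_transform(expr, config.pseudocount)
    if config.apply_gene_filter:
        expr = filter_informative_genes(expr, config.gene_filter)
    return expr


def run_sfcc_matrix(expr: ExpressionMatrix, config: RunConfig,
                    truth: LabelVector | None = None) -> RunReport:
    """Run the five SFCC steps on an in-memory matrix.

    Deterministic given the config seed. When ``truth`` is supplied the
    report's metrics block carries NMI/Rand/ARI against it plus the
    silhouette comparison between the original expression space and the
    feature space (median values and the fraction of cells improved).
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    work = _preprocess(expr, config)
    timings["preprocess"] = time.perf_counter() - t0
    log.info("preprocess: %d/%d genes retained, %d cells",
             work.n_genes, expr.n_genes, work.n_cells)

    t0 = time.perf_counter()
    plan = subsample(work.n_cells, config.rate, config.seed)
    timings["subsample"] = time.perf_counter() - t0
    log.info("subsample: %d anchors / %d rest (rate %.3g, seed %d)",
             plan.anchor_indices.size, plan.rest_indices.size,
             config.rate, config.seed)

    t0 = time.perf_counter()
    anchor_feats = build_features(work, plan.anchor_indices,
                                  plan.anchor_indices, config.feature)
    timings["featurize_anchors"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result = run_backend(config.backend, anchor_feats.values, config.k,
                         config.seed, **config.cluster_params)
    timings["cluster"] = time.perf_counter() - t0
    log.info("cluster: backend %s found %d clusters",
             config.backend, result.n_clusters)

    merged = np.empty(work.n_cells, dtype=int)
    merged[plan.anchor_indices] = np.asarray(result.labels.labels, dtype=int)
    t0 = time.perf_counter()
    if plan.rest_indices.size:
        rest_feats = build_features(work, plan.rest_indices,
                                    plan.anchor_indices, config.feature)
        anchor_ids = [work.cell_ids[i] for i in plan.anchor_indices]
        predicted = knn_classify(anchor_feats.values, result.labels,
                                 rest_feats.values,
                                 min(config.knn_k, plan.anchor_indices.size),
                                 train_ids=anchor_ids)
        merged[plan.rest_indices] = np.asarray(predicted.labels, dtype=int)
    timings["classify"] = time.perf_counter() - t0

    labels = LabelVector(merged)
    report = RunReport(
        labels=labels,
        cell_ids=list(work.cell_ids),
        anchor_indices=plan.anchor_indices,
        config={
            "feature": config.feature, "backend": config.backend,
            "k": config.k, "rate": config.rate, "knn_k": config.knn_k,
            "pseudocount": config.pseudocount,
            "gene_filter": vars(config.gene_filter),
            "apply_gene_filter": config.apply_gene_filter,
        },
        timings=timings,
        seed=config.seed,
    )
    if truth is not None:
        if len(truth) != work.n_cells:
            raise ValidationError(
                f"{len(truth)} truth labels for {work.n_cells} cells"
            )
        report.metrics = _evaluate_run(work, plan.anchor_indices, labels,
                                       truth, config)
    return report


def _full_feature_distances(work: ExpressionMatrix, anchors: np.ndarray,
                            feature: str) -> np.ndarray:
    """All-cells Euclidean distance matrix in the anchor feature space."""
    feats = build_features(work, np.arange(work.n_cells), anchors, feature)
    return squareform(pdist(feats.values))


def _full_feature_silhouette(work: ExpressionMatrix, anchors: np.ndarray,
                             labels: LabelVector, feature: str):
    """Silhouette of all cells under Euclidean distance in feature space."""
    return silhouette(_full_feature_distances(work, anchors, feature), labels)


def _evaluate_run(work: ExpressionMatrix, anchors: np.ndarray,
                  labels: LabelVector, truth: LabelVector,
                  config: RunConfig) -> dict:
    table = contingency(truth, labels)
    out = {
        "nmi": nmi(table),
        "rand": rand_index(table),
        "ari": adjusted_rand(table),
    }
    if truth.n_categories() >= 2:
        d_raw = squareform(pdist(work.cell_profiles()))
        s_before = silhouette(d_raw, truth)
        s_after = _full_feature_silhouette(work, anchors, truth, config.feature)
        out["median_silhouette_before"] = median_silhouette(s_before)
        out["median_silhouette_after"] = median_silhouette(s_after)
        out["fraction_improved"] = fraction_improved(s_before, s_after)
    return out


def run_sfcc(config: RunConfig) -> RunReport:
    """File-in, file-out pipeline run (CLI entry point)."""
    if config.input_path is None:
        raise ValidationError("config.input_path is required")
    expr = read_matrix(config.input_path, config.input_format,
                       scale_tag=config.scale_tag)
    truth = None
    if config.truth_path:
        truth_labels, truth_cells = read_labels(config.truth_path)
        if truth_cells != list(expr.cell_ids):
            raise ValidationError(
                "truth label cell ids do not match the expression matrix"
            )
        truth = truth_labels
    report = run_sfcc_matrix(expr, config, truth=truth)
    if config.out_prefix:
        prefix = Path(config.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_labels(report.labels, report.cell_ids,
                     Path(str(prefix) + ".labels.tsv"))
        Path(str(prefix) + ".report.json").write_text(
            report.to_json() + "\n", encoding="utf-8")
    return report


def evaluate_consistency(expr: ExpressionMatrix, config: RunConfig,
                         rate_a: float = 0.1, rate_b: float = 0.5,
                         n_repeats: int | None = None,
                         truth: LabelVector | None = None) -> dict:
    """Cross-rate consistency of the pipeline over seeded repeats.

    For each repeat r the pipeline runs at both rates with seed
    ``config.seed + r``; consistency is the NMI between the two
    full-cohort labelings (computed over all cells) and the Pearson
    correlation of their per-cell silhouette vectors, each cell scored
    with its run's predicted labels in that run's feature space. Means
    and standard deviations over the repeats are reported, along with
    per-repeat values and (when truth is given) per-rate accuracy.
    """
    if n_repeats is None:
        n_repeats = config.n_repeats
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    work = _preprocess(expr, config)
    bare = RunConfig(**{**vars(config), "apply_gene_filter": False,
                        "input_path": None, "out_prefix": None})
    consistency_nmi, sil_r, sil_truth_r = [], [], []
    acc_a, acc_b = [], []
    for r in range(n_repeats):
        seed_r = config.seed + r
        reports = {}
        for tag, rate in (("a", rate_a), ("b", rate_b)):
            cfg = RunConfig(**{**vars(bare), "rate": rate, "seed": seed_r})
            reports[tag] = run_sfcc_matrix(work, cfg)
        la, lb = reports["a"].labels, reports["b"].labels
        consistency_nmi.append(nmi(contingency(la, lb)))
        da = _full_feature_distances(work, reports["a"].anchor_indices,
                                     config.feature)
        db = _full_feature_distances(work, reports["b"].anchor_indices,
                                     config.feature)
        sil_r.append(pearson_correlation(silhouette(da, la).s,
                                         silhouette(db, lb).s))
        if truth is not None:
            acc_a.append(nmi(contingency(truth, la)))
            acc_b.append(nmi(contingency(truth, lb)))
            if truth.n_categories() >= 2:
                # subsampling stability of the feature space itself:
                # same (true) labels, the two rate spaces
                sil_truth_r.append(
                    pearson_correlation(silhouette(da, truth).s,
                                        silhouette(db, truth).s))
        log.info("repeat %d: consistency NMI %.3f, silhouette r %.3f",
                 r, consistency_nmi[-1], sil_r[-1])
    out = {
        "rate_a": rate_a, "rate_b": rate_b, "n_repeats": n_repeats,
        "feature": config.feature, "backend": config.backend,
        "consistency_nmi_mean": float(np.mean(consistency_nmi)),
        "consistency_nmi_sd": float(np.std(consistency_nmi, ddof=1))
        if n_repeats > 1 else 0.0,
        "silhouette_pearson_r_mean": float(np.mean(sil_r)),
        "silhouette_pearson_r_sd": float(np.std(sil_r, ddof=1))
        if n_repeats > 1 else 0.0,
        "consistency_nmi": [float(v) for v in consistency_nmi],
        "silhouette_pearson_r": [float(v) for v in sil_r],
    }
    if truth is not None:
        out["nmi_vs_truth_rate_a"] = [float(v) for v in acc_a]
        out["nmi_vs_truth_rate_b"] = [float(v) for v in acc_b]
        out["nmi_vs_truth_rate_a_mean"] = float(np.mean(acc_a))
        out["nmi_vs_truth_rate_b_mean"] = float(np.mean(acc_b))
        if sil_truth_r:
            out["silhouette_truth_pearson_r"] = [float(v) for v in sil_truth_r]
            out["silhouette_truth_pearson_r_mean"] = float(np.mean(sil_truth_r))
    return out
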