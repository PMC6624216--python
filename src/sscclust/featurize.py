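"""Feature construction: project cells onto anchor-cell similarity axes.

This is the step that turns SCC into SFCC. Each cell's feature vector is
its similarity (or distance) to every anchor cell, computed over the
filtered gene set. Anchors are featurized against themselves for
clustering; all other cells are projected into the *same* space for
classification, so the two stages share one geometry.

Methods: ``spearman`` (rank correlation — the SSCC choice), ``pearson``,
``cosine``, ``euclidean``, and ``identity`` (raw expression profiles,
the SCC baseline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .datamodel import ExpressionMatrix, NumericError, ValidationError

__all__ = ["FeatureMatrix", "build_features", "spearman_correlation",
           "FEATURE_METHODS"]

FEATURE_METHODS = ("spearman", "pearson", "cosine", "euclidean", "identity")


@dataclass
class FeatureMatrix:
    """Query-cells x anchor-cells feature matrix.

    ``anchor_ids`` name the feature axes (anchor cell ids, or gene ids in
    identity mode). Correlation/cosine entries lie in [-1, 1]; Euclidean
    entries are >= 0.
    """

    values: np.ndarray
    method_tag: str
    anchor_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.method_tag not in FEATURE_METHODS:
            raise ValidationError(
                f"method_tag must be one of {FEATURE_METHODS}, got {self.method_tag!r}"
            )
        if self.values.shape[1] != len(self.anchor_ids):
            raise ValidationError(
                f"{len(self.anchor_ids)} axis ids for {self.values.shape[1]} columns"
            )


def _require_nonconstant(profiles: np.ndarray, ids: Sequence[str], method: str) -> None:
    constant = np.flatnonzero(profiles.max(axis=1) == profiles.min(axis=1))
    if constant.size:
        names = [ids[i] for i in constant[:10]]
        raise NumericError(
            f"{method} correlation undefined for zero-variance cells: {names}"
        )


def _require_nonzero_norm(profiles: np.ndarray, ids: Sequence[str]) -> None:
    zero = np.flatnonzero(np.linalg.norm(profiles, axis=1) == 0)
    if zero.size:
        names = [ids[i] for i in zero[:10]]
        raise NumericError(f"cosine similarity undefined for zero-norm cells: {names}")


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm (Pearson building block)."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    return centered / norms


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson on fractional (average) ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("inputs must be equal-length vectors of size >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise NumericError("Spearman correlation undefined for a constant vector")
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / (np.linalg.norm(rx) * np.linalg.norm(ry)))


def build_features(expr: ExpressionMatrix, query: Sequence[int],
                   anchors: Sequence[int], method: str = "spearman",
                   chunk_size: int = 2048) -> FeatureMatrix:
    """Featurize ``query`` cells against ``anchors`` cells.

    Entry (q, a) applies ``method`` to the two cells' expression profiles
    over the current (filtered) gene set. ``identity`` ignores anchors and
    returns the raw profiles with gene ids as axes (SCC mode). Query rows
    are processed in chunks of ``chunk_size`` so memory stays linear in
    the anchor count.
    """
    query = np.asarray(query, dtype=int)
    anchors = np.asarray(anchors, dtype=int)
    if method not in FEATURE_METHODS:
        raise ValidationError(f"unknown feature method {method!r}")
    profiles = expr.cell_profiles()

    if method == "identity":
        return FeatureMatrix(profiles[query].copy(), "identity",
                             list(expr.gene_ids))

    if anchors.size == 0:
        raise ValidationError("anchor set must be nonempty")
    anchor_ids = [expr.cell_ids[i] for i in anchors]
    query_ids = [expr.cell_ids[i] for i in query]
    a_prof = profiles[anchors]
    q_prof = profiles[query]

    if method == "euclidean":
        out = np.empty((query.size, anchors.size))
        for lo in range(0, query.size, chunk_size):
            hi = min(lo + chunk_size, query.size)
            out[lo:hi] = cdist(q_prof[lo:hi], a_prof)
        return FeatureMatrix(out, method, anchor_ids)

    if method == "cosine":
        _require_nonzero_norm(a_prof, anchor_ids)
        _require_nonzero_norm(q_prof, query_ids)
        a_unit = a_prof / np.linalg.norm(a_prof, axis=1, keepdims=True)
        out = np.empty((query.size, anchors.size))
        for lo in range(0, query.size, chunk_size):
            hi = min(lo + chunk_size, query.size)
            q_unit = q_prof[lo:hi] / np.linalg.norm(
                q_prof[lo:hi], axis=1, keepdims=True)
            out[lo:hi] = np.clip(q_unit @ a_unit.T, -1.0, 1.0)
        return FeatureMatrix(out, method, anchor_ids)

    # pearson / spearman
    _require_nonconstant(a_prof, anchor_ids, method)
    _require_nonconstant(q_prof, query_ids, method)
    if method == "spearman":
        a_prof = rankdata(a_prof, axis=1)
        a_std = _standardize_rows(a_prof)
        out = np.empty((query.size, anchors.size))
        for lo in range(0, query.size, chunk_size):
            hi = min(lo + chunk_size, query.size)
            q_std = _standardize_rows(rankdata(q_prof[lo:hi], axis=1))
            out[lo:hi] = np.clip(q_std @ a_std.T, -1.0, 1.0)
        return FeatureMatrix(out, method, anchor_ids)

    a_std = _standardize_rows(a_prof)
    out = np.empty((query.size, anchors.size))
    for lo in range(0, query.size, chunk_size):
        hi = min(lo + chunk_size, query.size)
        out[lo:hi] = np.clip(_standardize_rows(q_prof[lo:hi]) @ a_std.T, -1.0, 1.0)
    return FeatureMatrix(out, "pearson", anchor_ids)
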