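"""Gene filtration and log transformation (pipeline step 1).

The informative-gene rule keeps genes whose log2-scale mean and standard
deviation both exceed a threshold (default 1), capped at the 5000 most
informative genes; datasets with fewer qualifying genes keep them all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExpressionMatrix, ValidationError

__all__ = ["GeneFilterSpec", "log2_transform", "filter_informative_genes",
           "filter_cells_min_genes"]


@dataclass
class GeneFilterSpec:
    """Thresholds for the informative-gene filter.

    mean_threshold / sd_threshold are in log2 expression units; ``cap``
    bounds the number of genes kept when more qualify.
    """

    mean_threshold: float = 1.0
    sd_threshold: float = 1.0
    cap: int = 5000

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise ValidationError(f"gene cap must be >= 1, got {self.cap}")
        if not (np.isfinite(self.mean_threshold) and np.isfinite(self.sd_threshold)):
            raise ValidationError("gene-filter thresholds must be finite")


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return log2(value + pseudocount) with scale_tag ``log2``.

    Refuses to transform twice; a pseudocount of 1 maps zero counts to
    zero log-expression.
    """
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount must be > 0, got {pseudocount}")
    if expr.scale_tag == "log2":
        raise ValidationError("matrix is already on log2 scale")
    return ExpressionMatrix(
        np.log2(expr.values + pseudocount),
        list(expr.gene_ids),
        list(expr.cell_ids),
        "log2",
    )


def filter_informative_genes(expr: ExpressionMatrix,
                             spec: GeneFilterSpec | None = None) -> ExpressionMatrix:
    """Keep the most informative genes of a log2-scale matrix.

    A gene qualifies when its per-gene mean and sample standard deviation
    (divisor n-1) both exceed the spec thresholds. When more than ``cap``
    genes qualify, the cap most informative are kept, ranked by sd
    descending, ties by mean descending, then original order; original
    gene order is preserved among survivors. Cells are untouched.
    """
    if spec is None:
        spec = GeneFilterSpec()
    if expr.scale_tag != "log2":
        raise ValidationError(
            f"gene filter expects log2-scale input, got {expr.scale_tag!r}"
        )
    means = expr.values.mean(axis=1)
    if expr.n_cells > 1:
        sds = expr.values.std(axis=1, ddof=1)
    else:
        sds = np.zeros(expr.n_genes)
    qualify = np.flatnonzero((means > spec.mean_threshold)
                             & (sds > spec.sd_threshold))
    if qualify.size == 0:
        raise ValidationError(
            "no genes pass the informative-gene filter "
            f"(mean > {spec.mean_threshold}, sd > {spec.sd_threshold}); "
            "relax the thresholds or check the input scale"
        )
    if qualify.size > spec.cap:
        # rank by informativeness: sd desc, mean desc, original order
        order = np.lexsort((qualify, -means[qualify], -sds[qualify]))
        keep = qualify[order[: spec.cap]]
        keep.sort()
    else:
        keep = qualify
    return expr.subset_genes(keep)


def filter_cells_min_genes(expr: ExpressionMatrix, min_genes: int) -> ExpressionMatrix:
    """Optional cell filter: keep cells expressing at least ``min_genes`` genes.

    Off by default in the pipeline (no published rule to reproduce);
    detection means a strictly positive value.
    """
    if min_genes < 0:
        raise ValidationError("min_genes must be >= 0")
    detected = (expr.values > 0).sum(axis=0)
    keep = np.flatnonzero(detected >= min_genes)
    if keep.size == 0:
        raise ValidationError(
            f"no cells express >= {min_genes} genes; relax the threshold"
        )
    return expr.subset_cells(keep)
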