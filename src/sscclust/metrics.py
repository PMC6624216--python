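"""Evaluation statistics for clustering runs.

Per-cell silhouette widths

    s_i = (b_i - a_i) / max{a_i, b_i}

with a_i the mean dissimilarity of cell i to its own cluster (self
excluded) and b_i the lowest mean dissimilarity to any other cluster;
normalized mutual information (NMI) between two partitions from their
contingency table; Rand and adjusted Rand indices; the fraction of cells
whose silhouette improves after feature projection; and plain Pearson
correlation for cross-rate silhouette comparisons.

NMI is computed as 2*I(A;B)/(H(A)+H(B)) with the 0*log 0 = 0 convention:
1 for identical partitions, 0 for independent ones, and 0 by convention
when either partition has a single cluster (degenerate denominator). The
log base cancels between numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import LabelVector, ValidationError

__all__ = [
    "ContingencyTable", "SilhouetteVector",
    "silhouette", "median_silhouette", "fraction_improved",
    "contingency", "nmi", "rand_index", "adjusted_rand",
    "pearson_correlation",
]


@dataclass
class ContingencyTable:
    """R x S table of shared cell counts between two clustering schemes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.size == 0:
            raise ValidationError("contingency table must be a nonempty 2-D matrix")
        if np.any(self.counts < 0):
            raise ValidationError("contingency counts must be nonnegative")

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class SilhouetteVector:
    """Per-cell silhouette widths with their a_i / b_i components."""

    s: np.ndarray
    a: np.ndarray
    b: np.ndarray


def silhouette(dissimilarity: np.ndarray, labels: LabelVector) -> SilhouetteVector:
    """Per-cell silhouette widths from a precomputed dissimilarity matrix.

    The matrix must be square, symmetric, nonnegative with a zero
    diagonal, and at least two clusters must be present. Cells in
    singleton clusters get s_i = 0 (Rousseeuw's convention), as does the
    degenerate case a_i = b_i = 0.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValidationError(f"dissimilarity must be {n}x{n}, got {d.shape}")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("dissimilarity matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValidationError("dissimilarity diagonal must be zero")
    if np.any(d < 0):
        raise ValidationError("dissimilarities must be nonnegative")
    codes = labels.codes()
    k = codes.max() + 1
    if k < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    sizes = np.bincount(codes, minlength=k)
    # mean dissimilarity of every cell to every cluster, n x k
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = d[:, codes == c].sum(axis=1)
    own = codes
    a = np.zeros(n)
    multi = sizes[own] > 1
    a[multi] = sums[np.arange(n), own][multi] / (sizes[own][multi] - 1)
    means = sums / sizes[None, :]
    means[np.arange(n), own] = np.inf  # exclude own cluster from b_i
    b = means.min(axis=1)
    denom = np.maximum(a, b)
    s = np.zeros(n)
    ok = denom > 0
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    s[sizes[own] == 1] = 0.0  # singleton convention
    return SilhouetteVector(s, a, b)


def median_silhouette(sv: SilhouetteVector) -> float:
    if sv.s.size == 0:
        raise ValidationError("empty silhouette vector")
    return float(np.median(sv.s))


def fraction_improved(s_before: SilhouetteVector, s_after: SilhouetteVector) -> float:
    """Fraction of cells whose silhouette strictly increases after projection."""
    if s_before.s.shape != s_after.s.shape:
        raise ValidationError("silhouette vectors must be aligned")
    if s_before.s.size == 0:
        raise ValidationError("empty silhouette vectors")
    return float(np.mean(s_after.s > s_before.s))


def contingency(a: LabelVector, b: LabelVector) -> ContingencyTable:
    """Cross-tabulate two clustering schemes over the same cells."""
    if len(a) != len(b):
        raise ValidationError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValidationError("empty label vectors")
    ca, cb = a.codes(), b.codes()
    r, s = ca.max() + 1, cb.max() + 1
    counts = np.zeros((r, s), dtype=np.int64)
    np.add.at(counts, (ca, cb), 1)
    return ContingencyTable(counts)


def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def nmi(table: ContingencyTable) -> float:
    """Normalized mutual information of two schemes from their table."""
    n = table.n
    if n < 1:
        raise ValidationError("contingency table is empty")
    ci = table.row_sums.astype(float)
    cj = table.col_sums.astype(float)
    h_a = -np.sum(_xlogx(ci / n))
    h_b = -np.sum(_xlogx(cj / n))
    if h_a == 0 or h_b == 0:
        return 0.0  # single-cluster scheme: degenerate denominator
    c = table.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = c * n / np.outer(ci, cj)
        terms = np.where(c > 0, c * np.log(np.where(c > 0, ratio, 1.0)), 0.0)
    mutual_info = terms.sum() / n
    return float(np.clip(2.0 * mutual_info / (h_a + h_b), 0.0, 1.0))


def _pair_counts(table: ContingencyTable) -> tuple[float, float, float, float]:
    c = table.counts.astype(float)
    n = table.n
    sum_c2 = (c * (c - 1) / 2).sum()
    sum_a2 = (table.row_sums * (table.row_sums - 1) / 2).sum()
    sum_b2 = (table.col_sums * (table.col_sums - 1) / 2).sum()
    total = n * (n - 1) / 2
    return sum_c2, sum_a2, sum_b2, total


def rand_index(table: ContingencyTable) -> float:
    """Fraction of cell pairs on which the two schemes agree."""
    sum_c2, sum_a2, sum_b2, total = _pair_counts(table)
    if total == 0:
        return 1.0
    agree = total + 2 * sum_c2 - sum_a2 - sum_b2
    return float(agree / total)


def adjusted_rand(table: ContingencyTable) -> float:
    """Rand index corrected for chance; 0 expected under independence."""
    sum_c2, sum_a2, sum_b2, total = _pair_counts(table)
    if total == 0:
        return 1.0
    expected = sum_a2 * sum_b2 / total
    max_index = (sum_a2 + sum_b2) / 2
    if max_index == expected:
        return 1.0  # both schemes trivial (all-singletons or one cluster)
    return float((sum_c2 - expected) / (max_index - expected))


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length nonconstant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("inputs must be equal-length vectors of size >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValidationError("Pearson correlation undefined for a constant vector")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))
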