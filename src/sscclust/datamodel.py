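"""Core data containers for the SSCC/SFCC pipeline.

The pipeline speaks one orientation everywhere: genes are rows, cells are
columns, matching the 10x on-disk convention. Expression values carry an
explicit scale tag (``counts``, ``tpm`` or ``log2``) so that transforms
can refuse to run twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "NumericError",
    "ExpressionMatrix",
    "LabelVector",
    "SCALE_TAGS",
]

SCALE_TAGS = ("counts", "tpm", "log2")


class ValidationError(ValueError):
    """Invalid inputs or broken invariants (CLI exit code 2)."""


class FormatError(ValidationError):
    """Malformed on-disk file (names the offending line where possible)."""


class NumericError(ArithmeticError):
    """Numeric failure such as an undefined correlation (CLI exit code 3)."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what}: {dups[:10]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifiers and a scale tag.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` float array. Counts/TPM must be
        finite and non-negative; log2-scale values only finite.
    gene_ids, cell_ids
        Unique row / column identifiers.
    scale_tag
        One of ``counts``, ``tpm``, ``log2``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.scale_tag not in SCALE_TAGS:
            raise ValidationError(
                f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}"
            )
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        ng, nc = self.values.shape
        if len(self.gene_ids) != ng:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {ng} matrix rows"
            )
        if len(self.cell_ids) != nc:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {nc} matrix columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.scale_tag in ("counts", "tpm") and np.any(self.values < 0):
            raise ValidationError(
                f"negative values not allowed on scale {self.scale_tag!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_profiles(self) -> np.ndarray:
        """Cells x genes view: one expression profile per row."""
        return self.values.T

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[index, :],
            [self.gene_ids[i] for i in index],
            list(self.cell_ids),
            self.scale_tag,
        )

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[:, index],
            list(self.gene_ids),
            [self.cell_ids[i] for i in index],
            self.scale_tag,
        )


@dataclass
class LabelVector:
    """Per-cell categorical cluster assignments.

    Comparisons between two label vectors (NMI, Rand, ARI) are invariant
    to any bijective renaming of the categories; the vector itself just
    stores the names aligned to a cell ordering.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be one-dimensional")

    def __len__(self) -> int:
        return int(self.labels.shape[0])

    def __iter__(self):
        return iter(self.labels)

    def codes(self) -> np.ndarray:
        """Integer codes (first-appearance order), for contingency counting."""
        _, codes = np.unique(self.labels, return_inverse=True)
        return codes

    def n_categories(self) -> int:
        return int(np.unique(self.labels).shape[0])

    def same_partition(self, other: "LabelVector") -> bool:
        """True if the two vectors induce the same partition of the cells."""
        if len(self) != len(other):
            return False
        a, b = self.codes(), other.codes()
        return bool(np.all(a == b) or len(np.unique(a * (b.max() + 1) + b))
                    == len(np.unique(a)) == len(np.unique(b)))
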