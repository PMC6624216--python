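"""Seeded random division of cells into anchors and the rest (step 2).

Anchor cells are the subsample that gets clustered; the rest are later
classified into the anchor-derived clusters. Sampling is uniform without
replacement and fully determined by (n_cells, rate, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ValidationError

__all__ = ["SplitPlan", "subsample"]


@dataclass
class SplitPlan:
    """A seeded partition of cell positions into anchors and rest."""

    anchor_indices: np.ndarray
    rest_indices: np.ndarray
    rate: float
    seed: int

    def __post_init__(self) -> None:
        self.anchor_indices = np.asarray(self.anchor_indices, dtype=int)
        self.rest_indices = np.asarray(self.rest_indices, dtype=int)

    @property
    def n_cells(self) -> int:
        return self.anchor_indices.size + self.rest_indices.size

    def to_json(self) -> str:
        return json.dumps({
            "rate": self.rate,
            "seed": self.seed,
            "anchor_indices": self.anchor_indices.tolist(),
            "rest_indices": self.rest_indices.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        obj = json.loads(text)
        return cls(np.array(obj["anchor_indices"], dtype=int),
                   np.array(obj["rest_indices"], dtype=int),
                   float(obj["rate"]), int(obj["seed"]))


def subsample(n_cells: int, rate: float, seed: int) -> SplitPlan:
    """Uniformly sample round(rate * n_cells) anchor cells without replacement.

    Rounding is half-up; at least 2 anchors are required (clustering is
    undefined below that). ``rate = 1`` keeps every cell as an anchor.
    Both index sets are returned sorted ascending.
    """
    if not (0.0 < rate <= 1.0):
        raise ValidationError(f"subsampling rate must be in (0, 1], got {rate}")
    if n_cells < 2:
        raise ValidationError(f"need at least 2 cells, got {n_cells}")
    n_anchors = int(np.floor(rate * n_cells + 0.5))
    if n_anchors < 2:
        raise ValidationError(
            f"rate {rate} of {n_cells} cells yields {n_anchors} anchors; "
            "at least 2 are needed for clustering"
        )
    rng = np.random.default_rng(seed)
    anchors = np.sort(rng.choice(n_cells, size=n_anchors, replace=False))
    rest = np.setdiff1d(np.arange(n_cells), anchors, assume_unique=True)
    return SplitPlan(anchors, rest, rate, seed)
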