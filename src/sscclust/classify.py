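"""k-nearest-neighbor label transfer in the shared feature space (step 5).

Every unsampled cell is labeled by majority vote among its k nearest
anchor cells under Euclidean distance on feature rows. Tie policies are
chosen to be independent of training-point order:

* distance ties at the k-th neighbor: neighbors sorted by
  (distance, training cell id), first k kept;
* vote ties: the tied class with the smallest summed distance over its
  voting neighbors wins; residual ties go to the smallest class id.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import LabelVector, ValidationError

__all__ = ["knn_classify"]


def knn_classify(train_features: np.ndarray, train_labels: LabelVector,
                 query_features: np.ndarray, k_neighbors: int = 5,
                 train_ids: Sequence[str] | None = None) -> LabelVector:
    """Classify query rows by k-nearest-neighbor vote over training rows.

    ``train_ids`` (defaults to stringified positions) only matter for
    breaking exact distance ties deterministically.
    """
    train = np.asarray(train_features, dtype=float)
    query = np.asarray(query_features, dtype=float)
    if train.ndim != 2 or query.ndim != 2:
        raise ValidationError("feature rows must form 2-D matrices")
    if train.shape[0] == 0:
        raise ValidationError("training set is empty")
    if train.shape[1] != query.shape[1]:
        raise ValidationError(
            f"feature axes differ: train has {train.shape[1]}, "
            f"query has {query.shape[1]}"
        )
    if len(train_labels) != train.shape[0]:
        raise ValidationError(
            f"{len(train_labels)} labels for {train.shape[0]} training rows"
        )
    if not 1 <= k_neighbors <= train.shape[0]:
        raise ValidationError(
            f"k_neighbors={k_neighbors} must be in [1, {train.shape[0]}]"
        )
    if train_ids is None:
        train_ids = [str(i) for i in range(train.shape[0])]
    id_order = np.argsort(np.asarray(train_ids, dtype=object))
    id_rank = np.empty(train.shape[0], dtype=int)
    id_rank[id_order] = np.arange(train.shape[0])

    labels = np.asarray(train_labels.labels)
    dist = cdist(query, train)
    out = np.empty(query.shape[0], dtype=labels.dtype)
    for qi in range(query.shape[0]):
        order = np.lexsort((id_rank, dist[qi]))
        nn = order[:k_neighbors]
        nn_labels = labels[nn]
        nn_dist = dist[qi, nn]
        classes, votes = np.unique(nn_labels, return_counts=True)
        top = classes[votes == votes.max()]
        if top.size == 1:
            out[qi] = top[0]
        else:
            # vote tie: smallest summed distance over the voting neighbors,
            # residual ties to the smallest class id
            sums = np.array([nn_dist[nn_labels == c].sum() for c in top])
            winners = top[sums == sums.min()]
            out[qi] = min(winners.tolist())
    return LabelVector(out)
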