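"""Disease-disease distances within one dimension, on a common [0, 1] scale.

Six metrics are computed on the binary feature profiles of each disease pair
(A and B denote the feature sets, over the union of the dimension's features):

========== =====================================================
euclidean  sqrt(|A xor B|), then divided by the matrix maximum
hamming    |A xor B|, then divided by the matrix maximum
cosine     1 - |A & B| / sqrt(|A| |B|)   (Ochiai coefficient on binary data)
jaccard    1 - |A & B| / |A | B|
dice       1 - 2 |A & B| / (|A| + |B|)
overlap    1 - |A & B| / min(|A|, |B|)
========== =====================================================

Similarity-based metrics are converted to distances as 1 - similarity.
Euclidean and Hamming are normalized per matrix by division by the maximum
entry (an all-identical input yields an all-zero matrix rather than 0/0).
Since overlap >= dice >= jaccard as similarities, the distances satisfy
overlap <= dice <= jaccard elementwise.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np

from .io_model import DistanceMatrix, FormatError, IncidenceMatrix

logger = logging.getLogger(__name__)

#: The closed set of metric names, in canonical order.
METRICS = ("euclidean", "hamming", "cosine", "jaccard", "dice", "overlap")

_SIMILARITY_METRICS = frozenset({"cosine", "jaccard", "dice", "overlap"})


def set_distance(metric: str, a: Iterable[str], b: Iterable[str], universe_size: int) -> float:
    """Reference scalar computation on two feature sets.

    For the similarity metrics the returned value is the final distance
    ``1 - similarity``; for euclidean/hamming it is the *raw* value, since
    their normalization is a per-matrix operation (division by the maximum).
    """
    if metric not in METRICS:
        raise FormatError(f"unknown metric {metric!r}; expected one of {METRICS}")
    sa, sb = set(a), set(b)
    if universe_size < len(sa | sb):
        raise FormatError("universe_size smaller than |A union B|")
    if metric in _SIMILARITY_METRICS and (not sa or not sb):
        raise FormatError(f"{metric}: undefined similarity for an empty feature set")
    inter = len(sa & sb)
    if metric == "jaccard":
        return 1.0 - inter / len(sa | sb)
    if metric == "dice":
        return 1.0 - 2.0 * inter / (len(sa) + len(sb))
    if metric == "overlap":
        return 1.0 - inter / min(len(sa), len(sb))
    if metric == "cosine":
        return 1.0 - inter / np.sqrt(len(sa) * len(sb))
    hamming = len(sa ^ sb)
    if metric == "hamming":
        return float(hamming)
    return float(np.sqrt(hamming))  # euclidean on binary vectors


def distance_matrix(inc: IncidenceMatrix, metric: str) -> DistanceMatrix:
    """All pairwise distances under one metric, normalized to [0, 1]."""
    if metric not in METRICS:
        raise FormatError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if inc.n_diseases < 2:
        raise FormatError("need >=2 diseases for a distance matrix")
    m = inc.values.astype(np.float64)
    sizes = m.sum(axis=1)
    if (sizes == 0).any():
        raise FormatError(
            f"dimension {inc.name!r}: diseases with no features present "
            "(apply coverage filtering first)"
        )
    inter = m @ m.T

    if metric in ("hamming", "euclidean"):
        raw = sizes[:, None] + sizes[None, :] - 2.0 * inter
        raw = np.maximum(raw, 0.0)
        if metric == "euclidean":
            raw = np.sqrt(raw)
        mx = raw.max()
        vals = raw / mx if mx > 0 else np.zeros_like(raw)
    elif metric == "jaccard":
        union = sizes[:, None] + sizes[None, :] - inter
        vals = 1.0 - inter / union
    elif metric == "dice":
        vals = 1.0 - 2.0 * inter / (sizes[:, None] + sizes[None, :])
    elif metric == "overlap":
        vals = 1.0 - inter / np.minimum(sizes[:, None], sizes[None, :])
    else:  # cosine
        vals = 1.0 - inter / np.sqrt(sizes[:, None] * sizes[None, :])

    vals = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(inc.disease_ids), vals)


def all_metric_matrices(inc: IncidenceMatrix) -> dict[str, DistanceMatrix]:
    """One distance matrix per metric, keyed by metric name."""
    return {metric: distance_matrix(inc, metric) for metric in METRICS}
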