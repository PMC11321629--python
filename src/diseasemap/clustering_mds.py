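"""Disease clustering on the consensus matrix, Dunn-index model selection,
and 2-D classical multidimensional scaling.

The disease map is partitioned by agglomerative ward.D2 clustering of the
consensus distance matrix.  The number of clusters is chosen by scanning the
Dunn index (minimum between-cluster distance over maximum within-cluster
diameter; higher means better separated) over tree cuts k = 2..k_max and
flagging plateau-aware local maxima; the selected k is user-overridable,
since the index typically rises with k and the interesting structure sits at
an interior local maximum.  Classical (Torgerson) MDS embeds the full
consensus matrix in the plane for display; coordinates of any disease subset
are sliced from the full embedding rather than re-fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .consensus_merge import MergeSchedule, ward_linkage
from .io_model import DistanceMatrix, FormatError

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Cluster label (1..k) per disease, in disease order."""

    disease_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.disease_ids),):
            raise FormatError("labels length does not match disease_ids")
        present = set(self.labels.tolist())
        if present != set(range(1, self.k + 1)):
            raise FormatError(f"labels must cover 1..{self.k}, got {sorted(present)}")

    def members(self, cluster_id: int) -> list[str]:
        return [d for d, l in zip(self.disease_ids, self.labels) if l == cluster_id]

    def sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in range(1, self.k + 1)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"disease_id": self.disease_ids, "cluster": self.labels})


def hclust_ward2(dist: DistanceMatrix) -> MergeSchedule:
    """ward.D2 dendrogram over diseases (deterministic index tie-breaks)."""
    return MergeSchedule(list(dist.disease_ids), ward_linkage(dist.values))


def cut_k(tree: MergeSchedule, k: int) -> ClusterAssignment:
    """Cut the dendrogram into exactly k clusters."""
    if not 2 <= k <= tree.n:
        raise FormatError(f"k={k} out of range 2..{tree.n}")
    return ClusterAssignment(list(tree.leaves), tree.cut(k), k)


def dunn_index(dist: DistanceMatrix, assign: ClusterAssignment) -> float:
    """min between-cluster distance / max within-cluster diameter.

    All-singleton (or duplicate-point) clusterings have zero maximal diameter
    and return +inf with a warning.
    """
    if assign.k < 2:
        raise FormatError("Dunn index needs k >= 2")
    if assign.disease_ids != dist.disease_ids:
        raise FormatError("assignment and distance matrix disagree on diseases")
    labels = assign.labels
    d = dist.values
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(labels), dtype=bool)
    between_min = float(d[~same].min())
    within = d[same & off_diag]
    diameter = float(within.max()) if within.size else 0.0
    if diameter == 0.0:
        warnings.warn(
            "maximum within-cluster diameter is zero; Dunn index is +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return between_min / diameter


@dataclass
class DunnScan:
    """Dunn index per cut k, with plateau-aware local-maximum flags."""

    ks: np.ndarray
    values: np.ndarray
    local_max: np.ndarray
    selected_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.ks, "dunn": self.values, "local_max": self.local_max}
        )


def _flag_local_maxima(values: np.ndarray) -> np.ndarray:
    """Flag maximal runs of equal values strictly above both neighbors."""
    flags = np.zeros(len(values), dtype=bool)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[j + 1] == values[i]:
            j += 1
        left_ok = i > 0 and values[i - 1] < values[i]
        right_ok = j < len(values) - 1 and values[j + 1] < values[i]
        if left_ok and right_ok:
            flags[i : j + 1] = True
        i = j + 1
    return flags


def dunn_scan(
    dist: DistanceMatrix,
    tree: MergeSchedule,
    k_max: int = 250,
    selected_k: int | None = None,
) -> DunnScan:
    """Dunn index over cuts k = 2..k_max of the dendrogram.

    The selected k is the first k of the flagged local-max run with the
    highest Dunn value (ties: smallest k); if no interior local maximum
    exists the global argmax is used.  ``selected_k`` overrides the choice.
    """
    n = tree.n
    k_hi = min(k_max, n - 1)
    if k_hi < 2:
        raise FormatError("need at least 3 diseases to scan cluster counts")
    ks = np.arange(2, k_hi + 1)
    vals = np.empty(len(ks))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, k in enumerate(ks):
            vals[i] = dunn_index(dist, cut_k(tree, int(k)))
    flags = _flag_local_maxima(vals)
    if selected_k is not None:
        if not 2 <= selected_k <= k_hi:
            raise FormatError(f"selected_k={selected_k} out of range 2..{k_hi}")
        chosen = int(selected_k)
    elif flags.any():
        best = np.flatnonzero(flags & (vals == vals[flags].max()))
        chosen = int(ks[best[0]])
    else:
        logger.warning("no interior Dunn local maximum; selecting global argmax")
        chosen = int(ks[int(np.argmax(vals))])
    return DunnScan(ks=ks, values=vals, local_max=flags, selected_k=chosen)


def classical_mds(dist: DistanceMatrix, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS coordinates from a distance matrix.

    Double-centers the squared distances, takes the top ``dims`` eigenpairs;
    negative eigenvalues among them (non-Euclidean input) are clipped to zero
    with a warning.  Column signs are fixed deterministically.
    """
    n = dist.n
    if dims > n - 1:
        raise FormatError(f"dims={dims} must be <= n-1 = {n - 1}")
    d2 = dist.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    top_vals = vals[order]
    if (top_vals < -1e-12 * max(1.0, abs(vals).max())).any():
        warnings.warn(
            "negative eigenvalues clipped to zero (distances are not Euclidean)",
            RuntimeWarning,
            stacklevel=2,
        )
    top_vals = np.clip(top_vals, 0.0, None)
    coords = vecs[:, order] * np.sqrt(top_vals)
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col.any():
            pivot = np.argmax(np.abs(col))
            if col[pivot] < 0:
                coords[:, c] = -col
    return pd.DataFrame(
        coords,
        index=pd.Index(dist.disease_ids, name="disease_id"),
        columns=[f"MDS{i + 1}" for i in range(dims)],
    )


def candidate_clusters(assign: ClusterAssignment, min_size: int = 5) -> list[int]:
    """Cluster ids with at least ``min_size`` diseases (reporting triage)."""
    return [c for c, s in assign.sizes().items() if s >= min_size]
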