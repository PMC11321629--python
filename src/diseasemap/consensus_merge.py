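"""Hierarchical consensus of a family of distance matrices.

The fusion rule: compute the pairwise Ipsen-Mikhailov distance among the
family members, cluster the members by agglomerative ward.D2 linkage on that
family distance, then average the matrices stepwise along the dendrogram -
each internal node's matrix is the unweighted arithmetic mean of its two
children's matrices, and the root matrix is the consensus.  The rule is
applied twice in the pipeline: once per dimension to fuse the six metric
matrices, and once to fuse the six dimension matrices into the final disease
map.

Because every internal node averages its two branches with weight 1/2
regardless of how many leaves each branch carries, the consensus is a convex
combination of the inputs with leaf weights equal to the product of 1/2 along
each root-to-leaf path.  Those effective weights are recorded in the output's
provenance: redundant matrices that merge early share one branch and hence
split its weight, while an outlier merging last keeps weight 1/2 on its own.

ward.D2 semantics: raw (unsquared) distances in, squares inside the
Lance-Williams recurrence, merge heights equal to the unsquared cluster
distance.  Ties are broken deterministically by the smallest (left, right)
node-index pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_model import DistanceMatrix, FormatError
from .spectral_distance import MatrixFamilyDistance, matrix_family_distance

logger = logging.getLogger(__name__)


@dataclass
class MergeSchedule:
    """Binary dendrogram over labeled leaves with merge heights.

    Node ids: leaves are 0..n-1 in ``leaves`` order; the t-th merge creates
    internal node n+t.  ``merges`` holds (left, right, height) with
    left < right; heights are non-decreasing under ward.D2.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]
    linkage: str = "ward.D2"

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise FormatError(
                f"schedule over {len(self.leaves)} leaves needs "
                f"{len(self.leaves) - 1} merges, got {len(self.merges)}"
            )

    @property
    def n(self) -> int:
        return len(self.leaves)

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels 1..k per leaf, cutting after the first n-k merges.

        Cluster ids are assigned in order of first member appearance over the
        ``leaves`` ordering.
        """
        n = self.n
        if not 1 <= k <= n:
            raise FormatError(f"k={k} out of range 1..{n}")
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for t, (a, b, _) in enumerate(self.merges[: n - k]):
            members[n + t] = members.pop(a) + members.pop(b)
        cluster_of_leaf = np.empty(n, dtype=int)
        for node, leaf_list in members.items():
            cluster_of_leaf[leaf_list] = node
        labels = np.zeros(n, dtype=int)
        next_id = 0
        seen: dict[int, int] = {}
        for i in range(n):
            node = cluster_of_leaf[i]
            if node not in seen:
                next_id += 1
                seen[node] = next_id
            labels[i] = seen[node]
        return labels

    def leaf_weights(self) -> np.ndarray:
        """Effective convex weight of each leaf in the stepwise average."""
        n = self.n
        weights: dict[int, np.ndarray] = {i: np.eye(n)[i] for i in range(n)}
        for t, (a, b, _) in enumerate(self.merges):
            weights[n + t] = 0.5 * (weights.pop(a) + weights.pop(b))
        (root_w,) = weights.values()
        return root_w

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n
        height = {i: 0.0 for i in range(n)}
        text = {i: _escape_newick(lbl) for i, lbl in enumerate(self.leaves)}
        for t, (a, b, h) in enumerate(self.merges):
            node = n + t
            height[node] = h
            text[node] = (
                f"({text.pop(a)}:{h - height.pop(a):.10g},"
                f"{text.pop(b)}:{h - height.pop(b):.10g})"
            )
        (root,) = text.values()
        return root + ";"


def _escape_newick(label: str) -> str:
    if any(c in label for c in "(),;: '\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def ward_linkage(distances: np.ndarray) -> list[tuple[int, int, float]]:
    """Agglomerative ward.D2 linkage on a square distance matrix.

    Vectorized Lance-Williams updates on squared distances; at every step the
    pair at minimal cluster distance is merged, ties resolved by the smallest
    (left, right) node-id pair; the recorded height is the unsquared cluster
    distance.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape != (n, n):
        raise FormatError(f"expected a square distance matrix, got {d.shape}")
    if n < 2:
        raise FormatError("need >=2 items to cluster")
    s = d ** 2
    np.fill_diagonal(s, np.inf)
    sizes = np.ones(n)
    ids = np.arange(n)
    alive = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        mval = s.min()
        cand = np.argwhere(np.triu(s <= mval, 1))
        pairs = sorted(
            (tuple(sorted((int(ids[i]), int(ids[j])))), (int(i), int(j)))
            for i, j in cand
        )
        (lo_id, hi_id), (pi, pj) = pairs[0]
        height = float(np.sqrt(mval))
        merges.append((lo_id, hi_id, height))

        others = alive.copy()
        others[[pi, pj]] = False
        ni, nj, nk = sizes[pi], sizes[pj], sizes[others]
        s_new = (
            (ni + nk) * s[pi, others] + (nj + nk) * s[pj, others] - nk * mval
        ) / (ni + nj + nk)
        s[pi, others] = s_new
        s[others, pi] = s_new
        sizes[pi] += sizes[pj]
        ids[pi] = next_id
        next_id += 1
        alive[pj] = False
        s[pj, :] = np.inf
        s[:, pj] = np.inf
        s[pi, pi] = np.inf
    return merges


def build_schedule(famdist: MatrixFamilyDistance) -> MergeSchedule:
    """ward.D2 dendrogram over a matrix family from its IM distances."""
    return MergeSchedule(list(famdist.labels), ward_linkage(famdist.values))


@dataclass
class ConsensusMatrix(DistanceMatrix):
    """A DistanceMatrix fused from a labeled family, with provenance."""

    source_labels: list[str] = field(default_factory=list)
    schedule: MergeSchedule | None = None
    weights: dict[str, float] = field(default_factory=dict)


def hierarchical_average(
    matrices: Sequence[DistanceMatrix], schedule: MergeSchedule
) -> ConsensusMatrix:
    """Stepwise arithmetic averaging of matrices along a merge schedule.

    ``matrices`` must be ordered to match ``schedule.leaves``.  Each internal
    node's matrix is (left + right) / 2 of its children's matrices (leaf or
    previously merged); the root matrix is returned, carrying the schedule
    and the effective leaf weights (which sum to 1) as provenance.
    """
    n = schedule.n
    if len(matrices) != n:
        raise FormatError(f"expected {n} matrices for schedule, got {len(matrices)}")
    ids = matrices[0].disease_ids
    for m in matrices[1:]:
        if m.disease_ids != ids:
            raise FormatError("matrices in a family must share disease ordering")
    node_vals: dict[int, np.ndarray] = {i: m.values for i, m in enumerate(matrices)}
    for t, (a, b, _) in enumerate(schedule.merges):
        node_vals[n + t] = 0.5 * (node_vals.pop(a) + node_vals.pop(b))
    (root,) = node_vals.values()
    w = schedule.leaf_weights()
    return ConsensusMatrix(
        disease_ids=list(ids),
        values=root,
        source_labels=list(schedule.leaves),
        schedule=schedule,
        weights={lbl: float(wi) for lbl, wi in zip(schedule.leaves, w)},
    )


def family_consensus(
    matrices: Sequence[DistanceMatrix],
    labels: Sequence[str],
    interpretation: str = "distance",
) -> tuple[ConsensusMatrix, MatrixFamilyDistance]:
    """IM family distance -> ward.D2 schedule -> stepwise average."""
    famdist = matrix_family_distance(matrices, labels, interpretation)
    schedule = build_schedule(famdist)
    consensus = hierarchical_average(matrices, schedule)
    logger.info(
        "consensus over %s: leaf weights %s",
        list(labels),
        {k: round(v, 4) for k, v in consensus.weights.items()},
    )
    return consensus, famdist


def metric_consensus(
    metric_matrices: Mapping[str, DistanceMatrix], interpretation: str = "distance"
) -> tuple[ConsensusMatrix, MatrixFamilyDistance]:
    """Fuse the per-metric matrices of one dimension into one matrix."""
    labels = list(metric_matrices)
    return family_consensus([metric_matrices[k] for k in labels], labels, interpretation)


def dimension_consensus(
    dimension_matrices: Mapping[str, DistanceMatrix], interpretation: str = "distance"
) -> tuple[ConsensusMatrix, MatrixFamilyDistance]:
    """Fuse the per-dimension consensus matrices into the final disease map."""
    labels = list(dimension_matrices)
    return family_consensus(
        [dimension_matrices[k] for k in labels], labels, interpretation
    )
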