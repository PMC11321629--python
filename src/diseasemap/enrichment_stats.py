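"""Feature enrichment over disease clusters and frequency/correlation reports.

For every feature and cluster, a 2x2 contingency table is formed over the
final disease set (associated / not associated x inside / outside the
cluster) and tested with Fisher's exact test: one-sided (over-representation,
greater tail) for the one-vs-all scan, one-sided for direct pairwise cluster
comparisons, two-sided for group-vs-group contrasts (e.g. cancer vs
non-cancer clusters).  Nominal p-values are Bonferroni-adjusted by
(number of clusters) x (number of features tested in the dimension), and
flagged significant below alpha = 0.05.

Also provided: per-feature disease-link frequency ranking (the "top features
per dimension" report) and Spearman rank correlations between association
degrees and external per-entity counts such as publication numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering_mds import ClusterAssignment
from .io_model import AssociationTable, FormatError, IncidenceMatrix

logger = logging.getLogger(__name__)

SIDES = ("one-greater", "two")

ALPHA = 0.05


@dataclass
class EnrichmentRecord:
    """One feature-vs-cluster 2x2 test.

    a: associated, in cluster;   b: associated, outside
    c: not associated, in;       d: not associated, outside
    """

    feature_id: str
    cluster_id: object
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_nominal: float
    p_adjusted: float
    sided: str
    haldane: bool = False

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


def fisher_p(a: int, b: int, c: int, d: int, sided: str = "one-greater") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    One-sided: upper tail P(X >= a) for over-representation in the first
    column; two-sided: sum of the probabilities of all tables (same margins)
    no more probable than the observed one.
    """
    if sided not in SIDES:
        raise FormatError(f"sided must be one of {SIDES}")
    if min(a, b, c, d) < 0:
        raise FormatError("negative cell count")
    n = a + b + c + d
    k_assoc = a + b
    n_in = a + c
    if sided == "one-greater":
        return float(stats.hypergeom.sf(a - 1, n, k_assoc, n_in))
    support = np.arange(max(0, k_assoc + n_in - n), min(k_assoc, n_in) + 1)
    pmf = stats.hypergeom.pmf(support, n, k_assoc, n_in)
    p_obs = stats.hypergeom.pmf(a, n, k_assoc, n_in)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """Sample odds ratio ad/bc; Haldane 0.5 correction only on a zero cell."""
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
        return (a2 * d2) / (b2 * c2), True
    return (a * d) / (b * c), False


def bonferroni_adjust(
    p_nominal: float | np.ndarray, n_clusters: int, n_features_dimension: int
) -> float | np.ndarray:
    """p * n_clusters * n_features, capped at 1."""
    if n_clusters < 1 or n_features_dimension < 1:
        raise FormatError("Bonferroni multipliers must be positive")
    adj = np.minimum(1.0, np.asarray(p_nominal, dtype=float) * n_clusters * n_features_dimension)
    return float(adj) if np.ndim(p_nominal) == 0 else adj


def fisher_one_vs_all(
    inc: IncidenceMatrix,
    assign: ClusterAssignment,
    cluster_id: int,
    sided: str = "one-greater",
    n_clusters: int | None = None,
    n_features_dimension: int | None = None,
) -> list[EnrichmentRecord]:
    """Over-representation of every feature in one cluster vs all others.

    ``inc`` must cover the assignment's disease set (restricted beforehand);
    the Bonferroni multipliers default to the assignment's k and the
    dimension's surviving feature count.
    """
    if assign.disease_ids != inc.disease_ids:
        raise FormatError("assignment and incidence matrix disagree on diseases")
    if cluster_id not in range(1, assign.k + 1):
        raise FormatError(f"cluster {cluster_id} not in 1..{assign.k}")
    n_clusters = assign.k if n_clusters is None else n_clusters
    n_features_dimension = (
        inc.n_features if n_features_dimension is None else n_features_dimension
    )
    mask = assign.labels == cluster_id
    n_in = int(mask.sum())
    n = inc.n_diseases
    a = inc.values[mask].sum(axis=0).astype(int)
    tot = inc.values.sum(axis=0).astype(int)
    present = tot > 0
    if not present.all():
        logger.warning(
            "dimension %r: %d features absent from all diseases skipped",
            inc.name, int((~present).sum()),
        )
    b = tot - a
    c = n_in - a
    d = (n - n_in) - b
    if sided == "one-greater":
        p = stats.hypergeom.sf(a - 1, n, tot, n_in)
    else:
        p = np.array([fisher_p(*t, sided="two") for t in zip(a, b, c, d)])
    p_adj = bonferroni_adjust(p, n_clusters, n_features_dimension)
    records = []
    for j, feat in enumerate(inc.feature_ids):
        if not present[j]:
            continue
        orr, hal = _odds_ratio(int(a[j]), int(b[j]), int(c[j]), int(d[j]))
        records.append(
            EnrichmentRecord(
                feature_id=feat,
                cluster_id=cluster_id,
                a=int(a[j]), b=int(b[j]), c=int(c[j]), d=int(d[j]),
                odds_ratio=float(orr),
                p_nominal=float(p[j]),
                p_adjusted=float(p_adj[j]),
                sided=sided,
                haldane=hal,
            )
        )
    return records


def _group_records(
    inc: IncidenceMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    sided: str,
    tag: str,
    n_clusters: int = 1,
    n_features_dimension: int | None = None,
) -> list[EnrichmentRecord]:
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise FormatError("both groups must be non-empty")
    if set_a & set_b:
        raise FormatError("groups must be disjoint")
    missing = (set_a | set_b) - set(inc.disease_ids)
    if missing:
        raise FormatError(f"diseases not in matrix: {sorted(missing)[:5]}")
    ia = [i for i, dd in enumerate(inc.disease_ids) if dd in set_a]
    ib = [i for i, dd in enumerate(inc.disease_ids) if dd in set_b]
    va = inc.values[ia]
    vb = inc.values[ib]
    n_features_dimension = (
        inc.n_features if n_features_dimension is None else n_features_dimension
    )
    records = []
    for j, feat in enumerate(inc.feature_ids):
        a = int(va[:, j].sum())
        b = int(vb[:, j].sum())
        if a + b == 0:
            continue
        c = len(ia) - a
        d = len(ib) - b
        p = fisher_p(a, b, c, d, sided=sided)
        orr, hal = _odds_ratio(a, b, c, d)
        records.append(
            EnrichmentRecord(
                feature_id=feat, cluster_id=tag,
                a=a, b=b, c=c, d=d,
                odds_ratio=float(orr), p_nominal=p,
                p_adjusted=float(bonferroni_adjust(p, n_clusters, n_features_dimension)),
                sided=sided, haldane=hal,
            )
        )
    return records


def fisher_pairwise(
    inc: IncidenceMatrix,
    cluster_a: Sequence[str],
    cluster_b: Sequence[str],
    sided: str = "one-greater",
    n_features_dimension: int | None = None,
) -> list[EnrichmentRecord]:
    """Direct comparison of feature frequencies between two clusters.

    The 2x2 table is (associated / not) x (cluster A / cluster B); the
    default one-sided test asks for over-representation in A.  Nominal
    p-values are the primary readout here; adjusted values are reported too.
    """
    return _group_records(
        inc, cluster_a, cluster_b, sided, tag="A_vs_B",
        n_features_dimension=n_features_dimension,
    )


def fisher_group_vs_group(
    inc: IncidenceMatrix,
    diseases_group_a: Sequence[str],
    diseases_group_b: Sequence[str],
    sided: str = "two",
    n_features_dimension: int | None = None,
) -> list[EnrichmentRecord]:
    """Two-sided contrast between two disease groups (e.g. cancer vs not)."""
    return _group_records(
        inc, diseases_group_a, diseases_group_b, sided, tag="groupA_vs_groupB",
        n_features_dimension=n_features_dimension,
    )


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Flat table of enrichment records (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "cluster": r.cluster_id,
                "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "odds_ratio": r.odds_ratio,
                "p_nominal": r.p_nominal,
                "p_adjusted": r.p_adjusted,
                "sided": r.sided,
                "haldane": r.haldane,
                "significant": r.significant,
            }
            for r in records
        ]
    )


def enrich_all_clusters(
    inc: IncidenceMatrix, assign: ClusterAssignment, sided: str = "one-greater"
) -> pd.DataFrame:
    """One-vs-all enrichment for every cluster of an assignment."""
    records: list[EnrichmentRecord] = []
    for c in range(1, assign.k + 1):
        records.extend(fisher_one_vs_all(inc, assign, c, sided=sided))
    return enrichment_frame(records)


def feature_frequency(table: AssociationTable, top_n: int | None = None) -> pd.DataFrame:
    """Features ranked by the number of linked diseases (descending).

    Ties are ordered lexicographically by feature id; ``rank`` is positional.
    """
    counts: dict[str, int] = {}
    for _, f in table.edges:
        counts[f] = counts.get(f, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        rows = rows[:top_n]
    return pd.DataFrame(
        {
            "feature_id": [f for f, _ in rows],
            "n_diseases_linked": [c for _, c in rows],
            "rank": np.arange(1, len(rows) + 1),
        }
    )


def spearman_report(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties) with its p-value.

    Accepts aligned arrays, or two pandas Series that are aligned on the
    intersection of their indices.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = sorted(set(x.index) & set(y.index))
        x = x.loc[common].to_numpy(dtype=float)
        y = y.loc[common].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FormatError("x and y must be aligned 1-D arrays")
    if len(x) < 3:
        raise FormatError("Spearman correlation needs n >= 3 pairs")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
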