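"""Synthetic six-dimension disease-feature data with planted cluster structure.

The generator emulates the statistical shape of multi-source disease
annotation data so that every pipeline stage is testable without downloads:

* K planted disease clusters whose signal is shared, with per-dimension
  fidelity, across the feature namespaces (each cluster owns a disjoint pool
  of signature features per namespace; members link signature features with
  probability ``p_in`` and any other feature with a popularity-weighted
  background probability derived from ``p_out``);
* heavy-tailed feature popularity: background linking probabilities scale
  with a power law over a per-namespace popularity ranking, producing hub
  features linked to a large fraction of diseases (the TNF / "pain" effect);
* partial disease coverage per dimension: each dimension observes only a
  random ``coverage`` fraction of the diseases, so the six dimensions overlap
  only partially and the cross-dimension intersection is a strict subset;
* a redundant pathway dimension derived deterministically from the gene
  dimension: genes are partitioned into pathways and a disease is linked to a
  pathway iff it is linked to at least one member gene.

Everything is deterministic for a fixed seed (per-dimension child generators
are spawned from a single root ``SeedSequence``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_model import AssociationTable, ConfigError, write_association_table

logger = logging.getLogger(__name__)

#: Generated dimensions, in canonical order.
DIMENSIONS = (
    "genes",
    "pathways",
    "chemicals_medicating",
    "symptoms",
    "chemicals_targeting",
    "chemicals_associated",
)

NAMESPACE_OF = {
    "genes": "gene",
    "pathways": "pathway",
    "chemicals_medicating": "chemical",
    "symptoms": "symptom",
    "chemicals_targeting": "chemical",
    "chemicals_associated": "chemical",
}

_FEATURE_PREFIX = {
    "genes": "g",
    "pathways": "pw",
    "chemicals_medicating": "cm",
    "symptoms": "sy",
    "chemicals_targeting": "ct",
    "chemicals_associated": "ca",
}

#: Dimensions with independently drawn features (pathways are derived).
_GENERATED = tuple(d for d in DIMENSIONS if d != "pathways")

_DEFAULT_FEATURES = {
    "genes": 150,
    "chemicals_medicating": 60,
    "symptoms": 80,
    "chemicals_targeting": 100,
    "chemicals_associated": 120,
}

#: Cap on popularity-boosted background probabilities, so hub features are
#: common but never deterministic.
_MAX_BACKGROUND_P = 0.8


def _per_dim(value, dims, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(dims) - set(value)
        if missing:
            raise ConfigError(f"{name}: missing dimensions {sorted(missing)}")
        return {d: float(value[d]) for d in dims}
    return {d: float(value) for d in dims}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults are the desk-scale conditions used throughout the test suite:
    60 diseases in 3 planted clusters, strong within-cluster signal
    (p_in=0.9) over a weak popularity-weighted background (p_out=0.05), and
    90% per-dimension disease coverage.
    """

    n_diseases: int = 60
    n_clusters: int = 3
    features_per_namespace: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_FEATURES)
    )
    p_in: float | dict[str, float] = 0.9
    p_out: float | dict[str, float] = 0.05
    popularity_exponent: float = 1.0
    coverage: float | dict[str, float] = 0.9
    genes_per_pathway: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_diseases:
            raise ConfigError("n_clusters must be <= n_diseases")
        if self.n_clusters < 1 or self.n_diseases < 2:
            raise ConfigError("need >=2 diseases and >=1 cluster")
        self._p_in = _per_dim(self.p_in, _GENERATED, "p_in")
        self._p_out = _per_dim(self.p_out, _GENERATED, "p_out")
        self._coverage = _per_dim(self.coverage, DIMENSIONS, "coverage")
        for dim in _GENERATED:
            if not (0 <= self._p_out[dim] < self._p_in[dim] <= 1):
                raise ConfigError(
                    f"{dim}: require 0 <= p_out < p_in <= 1, "
                    f"got p_out={self._p_out[dim]}, p_in={self._p_in[dim]}"
                )
        for dim in DIMENSIONS:
            if not (0 < self._coverage[dim] <= 1):
                raise ConfigError(f"{dim}: coverage must be in (0, 1]")
        if self.genes_per_pathway < 1:
            raise ConfigError("genes_per_pathway must be >= 1")
        missing = set(_GENERATED) - set(self.features_per_namespace)
        if missing:
            raise ConfigError(f"features_per_namespace missing {sorted(missing)}")


@dataclass
class GroundTruth:
    """Planted structure the generator used; the pipeline must recover it."""

    cluster_of: dict[str, int]
    present_in: dict[str, set[str]]
    pathway_members: dict[str, set[str]]

    def labels_for(self, disease_ids) -> np.ndarray:
        return np.array([self.cluster_of[d] for d in disease_ids], dtype=int)


def _feature_ids(dim: str, m: int) -> list[str]:
    p = _FEATURE_PREFIX[dim]
    return [f"{p}{i:05d}" for i in range(m)]


def _popularity_weights(m: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Power-law weights, mean 1, assigned to features in shuffled order."""
    ranks = np.arange(1, m + 1, dtype=float)
    w = ranks ** (-exponent)
    w /= w.mean()
    return w[rng.permutation(m)]


def derive_pathways(
    gene_edges: set[tuple[str, str]], pathway_members: Mapping[str, set[str]]
) -> set[tuple[str, str]]:
    """Disease-pathway edges: a disease links pathway P iff it links a gene of P."""
    genes_of: dict[str, set[str]] = {}
    for d, g in gene_edges:
        genes_of.setdefault(d, set()).add(g)
    out: set[tuple[str, str]] = set()
    for pw, members in pathway_members.items():
        for d, genes in genes_of.items():
            if genes & members:
                out.add((d, pw))
    return out


def generate(config: SyntheticConfig) -> tuple[dict[str, AssociationTable], GroundTruth]:
    """Generate six association tables plus the planted ground truth."""
    n, k = config.n_diseases, config.n_clusters
    diseases = [f"D{i:04d}" for i in range(n)]
    cluster_of = {d: (i % k) + 1 for i, d in enumerate(diseases)}
    labels = np.array([cluster_of[d] for d in diseases])

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(DIMENSIONS))
    rngs = {dim: np.random.default_rng(c) for dim, c in zip(DIMENSIONS, children)}

    full_edges: dict[str, set[tuple[str, str]]] = {}
    for dim in _GENERATED:
        rng = rngs[dim]
        m = int(config.features_per_namespace[dim])
        feats = _feature_ids(dim, m)
        sig_size = max(4, m // (2 * k))
        if sig_size * k > m:
            raise ConfigError(f"{dim}: too few features ({m}) for {k} signature pools")
        weights = _popularity_weights(m, config.popularity_exponent, rng)

        p = np.clip(config._p_out[dim] * weights, 0.0, _MAX_BACKGROUND_P)
        prob = np.tile(p, (n, 1))
        for c in range(1, k + 1):
            sig_cols = np.arange((c - 1) * sig_size, c * sig_size)
            prob[np.ix_(labels == c, sig_cols)] = config._p_in[dim]
        draws = rng.random((n, m)) < prob
        # guarantee every disease has >=1 feature in every dimension
        for i in np.flatnonzero(~draws.any(axis=1)):
            c = labels[i]
            j = int(rng.integers((c - 1) * sig_size, c * sig_size))
            draws[i, j] = True
        full_edges[dim] = {
            (diseases[i], feats[j]) for i, j in zip(*np.nonzero(draws))
        }

    # pathway dimension: deterministic function of the full gene edge set
    gene_feats = _feature_ids("genes", int(config.features_per_namespace["genes"]))
    gpp = config.genes_per_pathway
    pathway_members = {
        f"pw{p:05d}": set(gene_feats[p * gpp : (p + 1) * gpp])
        for p in range((len(gene_feats) + gpp - 1) // gpp)
    }
    full_edges["pathways"] = derive_pathways(full_edges["genes"], pathway_members)

    tables: dict[str, AssociationTable] = {}
    present_in: dict[str, set[str]] = {}
    for dim in DIMENSIONS:
        rng = rngs[dim]
        n_present = max(2, int(round(config._coverage[dim] * n)))
        present = set(
            np.array(diseases)[rng.choice(n, size=n_present, replace=False)]
        )
        edges = {(d, f) for d, f in full_edges[dim] if d in present}
        present_in[dim] = {d for d, _ in edges}
        tables[dim] = AssociationTable(dim, frozenset(edges), NAMESPACE_OF[dim])
        logger.info(
            "synthetic %s: %d diseases, %d features, %d edges",
            dim, len(present_in[dim]), len(tables[dim].features), len(edges),
        )

    return tables, GroundTruth(cluster_of, present_in, pathway_members)


def make_publication_counts(
    table: AssociationTable,
    correlation_strength: float,
    seed: int,
    entity: str = "feature",
) -> pd.Series:
    """Synthetic per-entity publication counts rank-correlated with degree.

    Counts are drawn through a Gaussian copula: a latent score mixes the
    normal scores of the degree ranks with independent noise at the requested
    strength, then is mapped monotonically to heavy-tailed positive integers.
    ``strength=1`` reproduces the degree ranking exactly (Spearman rho = 1);
    ``strength=0`` is independent noise.
    """
    if not (0 <= correlation_strength <= 1):
        raise ConfigError("correlation_strength must be in [0, 1]")
    if entity not in ("feature", "disease"):
        raise ConfigError("entity must be 'feature' or 'disease'")
    pos = 1 if entity == "feature" else 0
    deg: dict[str, int] = {}
    for edge in table.edges:
        deg[edge[pos]] = deg.get(edge[pos], 0) + 1
    ids = sorted(deg)
    degrees = np.array([deg[i] for i in ids], dtype=float)
    ranks = rankdata(degrees, method="average")
    gz = (ranks - ranks.mean()) / max(ranks.std(), 1e-12)
    rng = np.random.default_rng(seed)
    s = correlation_strength
    latent = s * gz + np.sqrt(max(0.0, 1 - s * s)) * rng.standard_normal(len(ids))
    counts = np.round(1e5 * np.exp(latent)).astype(np.int64)
    return pd.Series(counts, index=ids, name="n_publications")


# ---------------------------------------------------------------------------
# On-disk export
# ---------------------------------------------------------------------------


def write_tables(tables: Mapping[str, AssociationTable], out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for dim, table in tables.items():
        p = out_dir / f"{dim}.tsv"
        write_association_table(table, p)
        paths[dim] = p
    return paths


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "cluster_of": truth.cluster_of,
        "present_in": {d: sorted(s) for d, s in truth.present_in.items()},
        "pathway_members": {p: sorted(s) for p, s in truth.pathway_members.items()},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        cluster_of={d: int(c) for d, c in payload["cluster_of"].items()},
        present_in={d: set(s) for d, s in payload["present_in"].items()},
        pathway_members={p: set(s) for p, s in payload["pathway_members"].items()},
    )
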