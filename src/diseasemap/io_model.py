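"""Reading, writing, and filtering of disease-feature association data.

A *data dimension* is one bipartite layer linking diseases to features of a
single namespace: associated genes, associated pathways, medicating chemicals
(drugs), associated symptoms, chemicals targeting disease genes, or associated
chemicals.  Each dimension is an edge list on disk (two tab-separated columns:
disease id, feature id), converted here to a binary incidence matrix.

Before diseases can be compared across dimensions, two filters are applied:

1. per dimension, diseases whose feature count falls strictly below the first
   quartile of the count distribution are removed, so that poorly-annotated
   diseases do not distort the distance computation;
2. the surviving disease sets of all dimensions are intersected, so every
   disease used downstream has data in every dimension.

All disease orderings are lexicographic by identifier, which makes every
downstream tie-break deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Feature namespaces a dimension may use.
NAMESPACES = ("gene", "pathway", "chemical", "symptom")


class DiseaseMapError(Exception):
    """Base class for errors raised by this package."""


class FormatError(DiseaseMapError, ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(DiseaseMapError, ValueError):
    """Invalid configuration."""


class NumericError(DiseaseMapError, RuntimeError):
    """A numerical routine failed to converge or produced invalid output."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationTable:
    """One dimension's bipartite disease-feature edges.

    Edges are unordered and unweighted; duplicates are collapsed on load.
    Disease and feature identifiers live in disjoint namespaces.
    """

    dimension_name: str
    edges: frozenset[tuple[str, str]]
    feature_namespace: str = "gene"

    def __post_init__(self) -> None:
        if self.feature_namespace not in NAMESPACES:
            raise FormatError(
                f"unknown feature namespace {self.feature_namespace!r}; "
                f"expected one of {NAMESPACES}"
            )
        if not self.edges:
            raise FormatError(f"dimension {self.dimension_name!r} has no edges")
        for d, f in self.edges:
            if not d or not f:
                raise FormatError(
                    f"dimension {self.dimension_name!r}: empty identifier in edge {(d, f)!r}"
                )
        overlap = self.diseases & self.features
        if overlap:
            raise FormatError(
                f"dimension {self.dimension_name!r}: identifiers used both as "
                f"disease and feature: {sorted(overlap)[:5]}"
            )

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.edges)

    @property
    def features(self) -> frozenset[str]:
        return frozenset(f for _, f in self.edges)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class IncidenceMatrix:
    """Binary disease x feature membership matrix.

    Rows (diseases) and columns (features) are lexicographically ordered so
    the matrix is a pure function of the edge set.
    """

    disease_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.disease_ids), len(self.feature_ids)):
            raise FormatError(
                f"incidence shape {self.values.shape} does not match "
                f"{len(self.disease_ids)} diseases x {len(self.feature_ids)} features"
            )
        if self.values.size and self.values.max() > 1:
            raise FormatError("incidence matrix must be binary")
        if list(self.disease_ids) != sorted(self.disease_ids):
            raise FormatError("disease_ids must be lexicographically sorted")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_counts(self) -> np.ndarray:
        """Number of associated features per disease (row sums)."""
        return self.values.sum(axis=1, dtype=np.int64)

    def disease_counts(self) -> np.ndarray:
        """Number of associated diseases per feature (column sums)."""
        return self.values.sum(axis=0, dtype=np.int64)

    def features_of(self, disease_id: str) -> set[str]:
        i = self._disease_index(disease_id)
        row = self.values[i].astype(bool)
        return {f for f, keep in zip(self.feature_ids, row) if keep}

    def _disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"disease {disease_id!r} not in matrix {self.name!r}") from None

    def restrict_diseases(
        self, keep: Iterable[str], drop_empty_features: bool = True
    ) -> "IncidenceMatrix":
        """Restrict to a subset of diseases (result stays sorted)."""
        keep_set = set(keep)
        idx = [i for i, d in enumerate(self.disease_ids) if d in keep_set]
        sub = self.values[idx]
        feats = self.feature_ids
        if drop_empty_features:
            nonzero = sub.sum(axis=0) > 0
            sub = sub[:, nonzero]
            feats = [f for f, nz in zip(self.feature_ids, nonzero) if nz]
        return IncidenceMatrix(
            [self.disease_ids[i] for i in idx], list(feats), sub, name=self.name
        )


@dataclass(frozen=True)
class CoverageSummary:
    """Feature-count statistics per disease in one dimension."""

    dimension_name: str
    q1: float
    median: float
    mean: float
    q3: float
    n_diseases: int

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise FormatError(
                f"invalid coverage summary for {self.dimension_name!r}: "
                f"q1={self.q1}, median={self.median}, q3={self.q3}"
            )


@dataclass
class DistanceMatrix:
    """Square symmetric disease-disease distance matrix with entries in [0, 1]."""

    disease_ids: list[str]
    values: np.ndarray

    _SYM_TOL = 1e-12

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.disease_ids)
        if v.shape != (n, n):
            raise FormatError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if n and np.abs(v - v.T).max() > self._SYM_TOL:
            raise FormatError("distance matrix is not symmetric within 1e-12")
        if n and np.abs(np.diag(v)).max() > self._SYM_TOL:
            raise FormatError("distance matrix diagonal is not zero")
        if n and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise FormatError("distance entries must lie in [0, 1]")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.disease_ids)

    def distance(self, a: str, b: str) -> float:
        ia = self.disease_ids.index(a)
        ib = self.disease_ids.index(b)
        return float(self.values[ia, ib])

    def restrict(self, keep: Sequence[str]) -> "DistanceMatrix":
        keep_set = set(keep)
        idx = [i for i, d in enumerate(self.disease_ids) if d in keep_set]
        return DistanceMatrix(
            [self.disease_ids[i] for i in idx], self.values[np.ix_(idx, idx)]
        )


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------


def load_association_table(
    path: str | Path, dimension_name: str, feature_namespace: str = "gene"
) -> AssociationTable:
    """Read a two-column TSV edge list (disease_id, feature_id).

    Lines starting with '#' and blank lines are skipped.  A first data row
    equal to ``disease_id<TAB>feature_id`` is treated as a header.  Duplicate
    edges are collapsed; extra columns (e.g. weights) are ignored with a
    warning; a blank identifier is a hard parse error naming the line.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    warned_extra = False
    first_data = True
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns, got {len(parts)}"
                )
            d, f = parts[0].strip(), parts[1].strip()
            if first_data:
                first_data = False
                if (d.lower(), f.lower()) == ("disease_id", "feature_id"):
                    continue
            if not d or not f:
                raise FormatError(f"{path}:{lineno}: empty disease or feature identifier")
            if len(parts) > 2 and not warned_extra:
                logger.warning(
                    "%s: extra columns present (edge lists are unweighted); ignoring them",
                    path,
                )
                warned_extra = True
            edges.add((d, f))
    if not edges:
        raise FormatError(f"{path}: no edges found")
    logger.info("loaded %d edges for dimension %r from %s", len(edges), dimension_name, path)
    return AssociationTable(dimension_name, frozenset(edges), feature_namespace)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    """Write an edge list as sorted two-column TSV with a header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tfeature_id\n")
        for d, f in sorted(table.edges):
            fh.write(f"{d}\t{f}\n")


# ---------------------------------------------------------------------------
# Incidence construction and filtering
# ---------------------------------------------------------------------------


def to_incidence(table: AssociationTable) -> IncidenceMatrix:
    """Binary disease x feature matrix over the union of the table's features."""
    ds = sorted(table.diseases)
    fs = sorted(table.features)
    d_idx = {d: i for i, d in enumerate(ds)}
    f_idx = {f: i for i, f in enumerate(fs)}
    m = np.zeros((len(ds), len(fs)), dtype=np.uint8)
    for d, f in table.edges:
        m[d_idx[d], f_idx[f]] = 1
    return IncidenceMatrix(ds, fs, m, name=table.dimension_name)


def coverage_summary(inc: IncidenceMatrix) -> CoverageSummary:
    """Quartiles and mean of the per-disease feature-count distribution."""
    counts = inc.feature_counts()
    return CoverageSummary(
        dimension_name=inc.name,
        q1=float(np.quantile(counts, 0.25)),
        median=float(np.quantile(counts, 0.5)),
        mean=float(np.mean(counts)),
        q3=float(np.quantile(counts, 0.75)),
        n_diseases=inc.n_diseases,
    )


def filter_low_coverage(inc: IncidenceMatrix) -> tuple[IncidenceMatrix, CoverageSummary]:
    """Drop diseases whose feature count falls strictly below the first quartile.

    Q1 uses linear interpolation (quantile type 7); diseases tied exactly at Q1
    are retained.  The returned summary is computed on the pre-filter counts.
    """
    if inc.n_diseases < 4:
        raise FormatError(
            f"dimension {inc.name!r}: need >=4 diseases for quartile filtering, "
            f"have {inc.n_diseases}"
        )
    summary = coverage_summary(inc)
    counts = inc.feature_counts()
    keep = counts >= summary.q1
    if not keep.any():
        raise FormatError(f"dimension {inc.name!r} empty after filtering")
    kept_ids = [d for d, k in zip(inc.disease_ids, keep) if k]
    filtered = inc.restrict_diseases(kept_ids, drop_empty_features=True)
    logger.info(
        "dimension %r: quartile filter removed %d of %d diseases (Q1=%g)",
        inc.name, int((~keep).sum()), inc.n_diseases, summary.q1,
    )
    return filtered, summary


def intersect_diseases(incs: Sequence[IncidenceMatrix]) -> list[IncidenceMatrix]:
    """Restrict all matrices to the diseases present in every one of them.

    The returned matrices share the exact same ordered disease vector;
    features left without any disease are dropped per dimension.
    """
    if len(incs) < 2:
        raise FormatError("need at least two dimensions to intersect")
    common = set(incs[0].disease_ids)
    for inc in incs[1:]:
        common &= set(inc.disease_ids)
    if not common:
        raise FormatError("empty disease intersection across dimensions")
    logger.info("disease intersection across %d dimensions: %d diseases", len(incs), len(common))
    return [inc.restrict_diseases(common, drop_empty_features=True) for inc in incs]


def exclude_unnamed(
    incs: Sequence[IncidenceMatrix],
    name_map: Mapping[str, str],
    strict: bool = False,
) -> list[IncidenceMatrix]:
    """Remove diseases that have no display name in ``name_map``.

    An empty map with ``strict=False`` is a documented pass-through (no
    annotation available, nothing removed); with ``strict=True`` it removes
    everything and therefore errors.
    """
    if not name_map and not strict:
        return list(incs)
    named = {d for inc in incs for d in inc.disease_ids if d in name_map}
    out = []
    for inc in incs:
        keep = [d for d in inc.disease_ids if d in named]
        if not keep:
            raise FormatError(f"dimension {inc.name!r}: no named diseases remain")
        out.append(inc.restrict_diseases(keep, drop_empty_features=True))
    removed = len(set(incs[0].disease_ids)) - len(set(out[0].disease_ids))
    if removed:
        logger.info("excluded %d diseases without names", removed)
    return out


# ---------------------------------------------------------------------------
# Matrix / table I/O
# ---------------------------------------------------------------------------


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square TSV with disease ids as header row and first column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(dm.values, index=dm.disease_ids, columns=dm.disease_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column identifiers differ")
    return DistanceMatrix([str(x) for x in df.index], df.to_numpy(dtype=float))


def write_coverage_summaries(
    summaries: Sequence[CoverageSummary], path: str | Path
) -> None:
    """Coverage statistics table (one row per dimension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "dimension": s.dimension_name,
                "n_diseases": s.n_diseases,
                "q1": s.q1,
                "median": s.median,
                "mean": s.mean,
                "q3": s.q3,
            }
            for s in summaries
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_name_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: disease_id -> display name ('#' comments allowed)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip():
                raise FormatError(f"{path}:{lineno}: expected disease_id<TAB>name")
            if parts[0].strip().lower() == "disease_id" and lineno == 1:
                continue
            out[parts[0].strip()] = parts[1].strip()
    return out
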