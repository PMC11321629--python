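"""Disease-centric queries and comparison against the ICD-10 classification.

Neighborhood queries rank the k nearest diseases of a query disease on the
consensus map; shared-feature queries extract features common to a disease
pair while excluding those carried by confounder diseases (e.g. features of
generic inflammation); rarity counts report, on a dimension's full filtered
disease universe, how many *further* diseases carry a feature beyond a given
pair.

The ICD-10 comparison converts a disease -> ICD-10 code mapping into a
distance matrix via a hierarchical code-similarity rule (identical codes are
fully similar; sharing the three-character category or only the chapter
letter gives graded partial similarity) and places that matrix inside the
Ipsen-Mikhailov family comparison next to the data dimensions and their
consensus, restricted to the mapped diseases.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import DistanceMatrix, FormatError, IncidenceMatrix
from .spectral_distance import MatrixFamilyDistance, matrix_family_distance

logger = logging.getLogger(__name__)

#: letter + two digits, optional subcategory digits after a dot
ICD_CODE_RE = re.compile(r"^[A-Z]\d{2}(?:\.\d{1,4})?$")


@dataclass
class NeighborhoodReport:
    """Top-k similar diseases of one query disease on the consensus map."""

    disease_id: str
    neighbors: list[tuple[str, float]]
    tied_at_cutoff: bool = False
    tags: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "query": self.disease_id,
                "neighbor": [d for d, _ in self.neighbors],
                "consensus_distance": [x for _, x in self.neighbors],
                "rank": np.arange(1, len(self.neighbors) + 1),
                "tag": [self.tags.get(d, "") for d, _ in self.neighbors],
            }
        )


def top_k_neighbors(
    consensus: DistanceMatrix,
    disease_id: str,
    k: int = 10,
    tags: Mapping[str, str] | None = None,
) -> NeighborhoodReport:
    """k nearest diseases by consensus distance (ties broken lexicographically).

    The query disease is excluded from its own list; if the k-th and (k+1)-th
    distances tie, the report flags the cutoff as tied.
    """
    if disease_id not in consensus.disease_ids:
        raise FormatError(f"disease {disease_id!r} not in consensus matrix")
    if k < 1:
        raise FormatError("k must be >= 1")
    i = consensus.disease_ids.index(disease_id)
    pairs = [
        (d, float(consensus.values[i, j]))
        for j, d in enumerate(consensus.disease_ids)
        if j != i
    ]
    pairs.sort(key=lambda p: (p[1], p[0]))
    k = min(k, len(pairs))
    tied = k < len(pairs) and pairs[k - 1][1] == pairs[k][1]
    if tied:
        logger.warning(
            "%s: distance tie at the top-%d cutoff (%.6g)", disease_id, k, pairs[k - 1][1]
        )
    return NeighborhoodReport(
        disease_id=disease_id,
        neighbors=pairs[:k],
        tied_at_cutoff=tied,
        tags=dict(tags or {}),
    )


def shared_exclusive_features(
    inc: IncidenceMatrix,
    pair: tuple[str, str],
    exclude: Sequence[str] = (),
) -> set[str]:
    """features(d1) & features(d2) minus the union over excluded diseases."""
    d1, d2 = pair
    shared = inc.features_of(d1) & inc.features_of(d2)
    for d in exclude:
        shared -= inc.features_of(d)
    return shared


def feature_rarity(
    inc: IncidenceMatrix,
    feature_id: str,
    exclude_pair: Sequence[str] = (),
) -> int:
    """Number of diseases linked to a feature, beyond an optional pair.

    Counted on the dimension's full (post-quartile-filter, pre-intersection)
    disease universe, so rarity reflects the whole data layer.
    """
    try:
        j = inc.feature_ids.index(feature_id)
    except ValueError:
        raise FormatError(f"feature {feature_id!r} not in dimension {inc.name!r}") from None
    col = inc.values[:, j].astype(bool)
    total = int(col.sum())
    covered = sum(
        1
        for d in exclude_pair
        if d in inc.disease_ids and col[inc.disease_ids.index(d)]
    )
    return total - covered


# ---------------------------------------------------------------------------
# ICD-10
# ---------------------------------------------------------------------------


def _parse_icd(code: str) -> tuple[str, str, str]:
    code = code.strip().upper()
    if not ICD_CODE_RE.match(code):
        raise FormatError(f"malformed ICD-10 code {code!r}")
    return code[0], code[:3], code


def icd10_similarity(
    code_a: str,
    code_b: str,
    strategy: Callable[[str, str], float] | None = None,
) -> float:
    """Hierarchical-level similarity of two ICD-10 codes in [0, 1].

    Default rule: deepest shared level / 3, with levels (chapter letter,
    three-character category, full code); identical codes score 1.  A custom
    ``strategy`` replaces the rule entirely (e.g. a published block-aware
    formula).
    """
    if strategy is not None:
        return float(strategy(code_a, code_b))
    la, ca, fa = _parse_icd(code_a)
    lb, cb, fb = _parse_icd(code_b)
    if fa == fb:
        return 1.0
    if ca == cb:
        return 2.0 / 3.0
    if la == lb:
        return 1.0 / 3.0
    return 0.0


def read_icd_mapping(path: str | Path) -> dict[str, str]:
    """TSV disease_id -> ICD-10 code (optional third match-quality column)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(f"{path}:{lineno}: expected disease_id<TAB>icd10_code")
            if parts[0].strip().lower() == "disease_id" and lineno == 1:
                continue
            code = parts[1].strip().upper()
            _parse_icd(code)
            out[parts[0].strip()] = code
    return out


def icd_distance_matrix(
    mapping: Mapping[str, str],
    diseases: Sequence[str],
    strategy: Callable[[str, str], float] | None = None,
) -> DistanceMatrix:
    """1 - ICD similarity over a disease set that the mapping fully covers."""
    missing = [d for d in diseases if d not in mapping]
    if missing:
        raise FormatError(f"diseases without ICD code: {missing[:5]}")
    n = len(diseases)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = icd10_similarity(mapping[diseases[i]], mapping[diseases[j]], strategy)
            vals[i, j] = vals[j, i] = 1.0 - s
    return DistanceMatrix(list(diseases), vals)


def icd_compare(
    dimension_matrices: Mapping[str, DistanceMatrix],
    consensus: DistanceMatrix,
    mapping: Mapping[str, str],
    interpretation: str = "distance",
    strategy: Callable[[str, str], float] | None = None,
) -> MatrixFamilyDistance:
    """IM family distance among dimensions, consensus, and the ICD-10 matrix.

    All matrices are restricted to the mapped subset of the consensus disease
    set (at least 3 diseases required), mirroring how only the ICD-mappable
    diseases can enter the comparison.
    """
    mapped = sorted(set(consensus.disease_ids) & set(mapping))
    if len(mapped) < 3:
        raise FormatError(
            f"ICD mapping covers only {len(mapped)} consensus diseases (need >=3)"
        )
    logger.info(
        "ICD comparison restricted to %d of %d diseases", len(mapped), consensus.n
    )
    labels = list(dimension_matrices) + ["consensus", "ICD10"]
    matrices = [dimension_matrices[k].restrict(mapped) for k in dimension_matrices]
    matrices.append(consensus.restrict(mapped))
    matrices.append(icd_distance_matrix(mapping, mapped, strategy))
    return matrix_family_distance(matrices, labels, interpretation)
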