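"""End-to-end orchestration: edge lists in, disease map and reports out.

Stages (each writes its outputs under the configured directory):

1. load the six dimension edge lists and build incidence matrices;
2. lower-quartile coverage filtering per dimension (optional), disease
   intersection across dimensions, optional removal of unnamed diseases;
3. six metric distance matrices per dimension and their IM-guided metric
   consensus;
4. IM comparison of the six dimension matrices and the dimension-level
   consensus (the disease map);
5. ward.D2 clustering, Dunn scan with model selection, classical MDS;
6. one-vs-all feature enrichment per dimension and cluster;
7. neighborhood reports for configured query diseases; optional ICD-10
   comparison.

A JSON run manifest records the configuration hash, library versions,
calibrated gamma values, consensus leaf weights, and per-stage disease
counts, sufficient to reproduce every output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering_mds import (
    candidate_clusters,
    classical_mds,
    cut_k,
    dunn_scan,
    hclust_ward2,
)
from .consensus_merge import dimension_consensus, metric_consensus
from .enrichment_stats import enrich_all_clusters
from .io_model import (
    ConfigError,
    DiseaseMapError,
    coverage_summary,
    exclude_unnamed,
    filter_low_coverage,
    intersect_diseases,
    load_association_table,
    read_name_map,
    to_incidence,
    write_coverage_summaries,
    write_distance_matrix,
)
from .neighborhood_icd import icd_compare, read_icd_mapping, top_k_neighbors
from .pairwise_metrics import all_metric_matrices
from .spectral_distance import write_family_distance
from .synthetic_data import NAMESPACE_OF

logger = logging.getLogger(__name__)


class PipelineError(DiseaseMapError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for a full run; thresholds default to the study's rules."""

    dimension_files: dict[str, str]
    out_dir: str = "results"
    feature_namespaces: dict[str, str] = field(default_factory=dict)
    apply_quartile_filter: bool = True
    adjacency_interpretation: str = "distance"
    k_max: int = 250
    selected_k: int | None = None
    name_map: str | None = None
    strict_names: bool = False
    icd_mapping: str | None = None
    query_diseases: list[str] = field(default_factory=list)
    top_k: int = 10
    min_cluster_size: int = 5
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dimension_files) < 2:
            raise ConfigError("need at least two dimension files")
        for dim, path in self.dimension_files.items():
            if not Path(path).is_file():
                raise ConfigError(f"dimension {dim!r}: file not found: {path}")
        for name in ("name_map", "icd_mapping"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise ConfigError(f"{name}: file not found: {p}")
        if self.k_max < 2:
            raise ConfigError("k_max must be >= 2")
        if len(self.dimension_files) != 6:
            logger.warning(
                "running with %d dimensions (the reference design uses six)",
                len(self.dimension_files),
            )

    def namespace_of(self, dim: str) -> str:
        if dim in self.feature_namespaces:
            return self.feature_namespaces[dim]
        return NAMESPACE_OF.get(dim, "gene")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except DiseaseMapError as exc:
        raise PipelineError(f"stage {name!r}: {exc}") from exc
    logger.info("stage %s: done", name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
    }

    with _stage("load"):
        tables = {
            dim: load_association_table(path, dim, config.namespace_of(dim))
            for dim, path in config.dimension_files.items()
        }
        incs = {dim: to_incidence(t) for dim, t in tables.items()}
        manifest["n_diseases_loaded"] = {d: m.n_diseases for d, m in incs.items()}

    with _stage("filter"):
        summaries = []
        if config.apply_quartile_filter:
            filtered = {}
            for dim, inc in incs.items():
                f, s = filter_low_coverage(inc)
                filtered[dim] = f
                summaries.append(s)
            incs = filtered
        else:
            summaries = [coverage_summary(m) for m in incs.values()]
        post = [coverage_summary(m) for m in incs.values()]
        write_coverage_summaries(summaries, out / "coverage_prefilter.tsv")
        write_coverage_summaries(post, out / "coverage_postfilter.tsv")
        dims = list(incs)
        intersected = dict(zip(dims, intersect_diseases([incs[d] for d in dims])))
        if config.name_map is not None:
            name_map = read_name_map(config.name_map)
            intersected = dict(
                zip(
                    dims,
                    exclude_unnamed(
                        [intersected[d] for d in dims], name_map, config.strict_names
                    ),
                )
            )
        disease_ids = intersected[dims[0]].disease_ids
        manifest["n_diseases_final"] = len(disease_ids)
        manifest["n_diseases_filtered"] = {d: m.n_diseases for d, m in incs.items()}

    with _stage("metric-distances"):
        per_dim_metrics = {}
        dim_consensus = {}
        metric_weights = {}
        for dim, inc in intersected.items():
            mats = all_metric_matrices(inc)
            per_dim_metrics[dim] = mats
            cons, fam = metric_consensus(mats, config.adjacency_interpretation)
            dim_consensus[dim] = cons
            metric_weights[dim] = cons.weights
            ddir = out / "dimensions" / dim
            for metric, m in mats.items():
                write_distance_matrix(m, ddir / f"distance_{metric}.tsv")
            write_distance_matrix(cons, ddir / "consensus.tsv")
            write_family_distance(fam, ddir / "metric_im_distance.tsv")
            (ddir / "metric_dendrogram.nwk").write_text(cons.schedule.to_newick() + "\n")
        manifest["metric_leaf_weights"] = metric_weights
        manifest["gamma_diseases"] = fam.gamma

    with _stage("dimension-consensus"):
        consensus, dim_fam = dimension_consensus(
            dim_consensus, config.adjacency_interpretation
        )
        write_distance_matrix(consensus, out / "consensus_map.tsv")
        write_family_distance(dim_fam, out / "dimension_im_distance.tsv")
        (out / "dimension_dendrogram.nwk").write_text(
            consensus.schedule.to_newick() + "\n"
        )
        manifest["dimension_leaf_weights"] = consensus.weights

    with _stage("clustering"):
        tree = hclust_ward2(consensus)
        scan = dunn_scan(consensus, tree, config.k_max, config.selected_k)
        assign = cut_k(tree, scan.selected_k)
        scan.to_frame().to_csv(out / "dunn_scan.tsv", sep="\t", index=False)
        assign.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
        coords = classical_mds(consensus, dims=2)
        coords.to_csv(out / "mds_coordinates.tsv", sep="\t", float_format="%.17g")
        (out / "disease_dendrogram.nwk").write_text(tree.to_newick() + "\n")
        manifest["selected_k"] = scan.selected_k
        manifest["candidate_clusters"] = candidate_clusters(
            assign, config.min_cluster_size
        )

    with _stage("enrichment"):
        for dim, inc in intersected.items():
            frame = enrich_all_clusters(inc, assign)
            frame.to_csv(
                out / "dimensions" / dim / "enrichment_one_vs_all.tsv",
                sep="\t", index=False, float_format="%.6g",
            )

    with _stage("neighborhoods"):
        reports = [
            top_k_neighbors(consensus, d, config.top_k)
            for d in config.query_diseases
        ]
        if reports:
            pd.concat([r.to_frame() for r in reports]).to_csv(
                out / "neighborhoods.tsv", sep="\t", index=False, float_format="%.17g"
            )

    if config.icd_mapping is not None:
        with _stage("icd-compare"):
            mapping = read_icd_mapping(config.icd_mapping)
            fam = icd_compare(
                dim_consensus, consensus, mapping, config.adjacency_interpretation
            )
            write_family_distance(fam, out / "icd_im_distance.tsv")
            manifest["n_diseases_icd"] = len(
                set(consensus.disease_ids) & set(mapping)
            )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
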