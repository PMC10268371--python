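"""End-to-end evaluation pipeline.

The framework takes a set of molecules with curated taxon labels and a
pairwise dissimilarity source -- a precomputed distance CSV, a
per-molecule (s, e) feature CSV, or a folder of structure files plus a
comparison method -- and, for each requested linkage, clusters the
molecules into as many groups as there are distinct taxon labels and
scores the partition with rand index, homogeneity and completeness.

The framework is method-agnostic at the distance boundary: any
external tool's dissimilarity CSV is accepted unchanged.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import aspra, rag2d, topology
from .clustering import (
    DistanceMatrix,
    LINKAGES,
    agglomerative_cluster,
    num_clusters_from_labels,
)
from .io import (
    SecondaryStructure,
    parse_bpseq,
    parse_ct,
    parse_dotbracket,
    write_bpseq,
    write_dotbracket,
)
from .metrics import MetricReport, score_partition
from .synthetic import GeneratorConfig, gen_labeled_set

logger = logging.getLogger(__name__)

METHODS = ("genus", "pskorder", "aspra", "rag2d")

_PARSERS = {
    ".bpseq": parse_bpseq,
    ".ct": parse_ct,
    ".db": parse_dotbracket,
    ".dbn": parse_dotbracket,
    ".dot": parse_dotbracket,
}


class PipelineError(ValueError):
    pass


def load_structure_file(path: Path) -> SecondaryStructure:
    """Parse one structure file, format auto-detected by extension."""
    parser = _PARSERS.get(path.suffix.lower())
    if parser is None:
        raise PipelineError(f"unsupported structure format: {path.name}")
    try:
        return parser(path.read_text())
    except ValueError as exc:
        raise PipelineError(f"unparseable structure file {path.name}: {exc}") from exc


def load_structure_folder(folder: Path) -> Tuple[List[str], List[SecondaryStructure]]:
    """All structure files of *folder*, sorted by file stem (= molecule ID)."""
    paths = sorted(
        (p for p in Path(folder).iterdir() if p.suffix.lower() in _PARSERS),
        key=lambda p: p.stem,
    )
    if not paths:
        raise PipelineError(f"no structure files in {folder}")
    return [p.stem for p in paths], [load_structure_file(p) for p in paths]


# ---------------------------------------------------------------------------
# distance computation
# ---------------------------------------------------------------------------

def distance_matrix_from_structures(
    ids: Sequence[str],
    structures: Sequence[SecondaryStructure],
    method: str,
) -> DistanceMatrix:
    """Pairwise dissimilarities over *structures* with one comparison method.

    Per-molecule methods (genus, pskorder, rag2d) evaluate each
    molecule once and compare summaries; the ASPRA method aligns every
    pair of structural trees.
    """
    if method not in METHODS:
        raise PipelineError(f"unknown method {method!r}; use one of {METHODS}")
    n = len(structures)
    start = time.perf_counter()
    values = np.zeros((n, n))
    if method == "genus":
        g = [topology.genus(s).genus for s in structures]
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = abs(g[i] - g[j])
    elif method == "pskorder":
        o = [topology.pseudoknot_order(s).structure_order for s in structures]
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = abs(o[i] - o[j])
    elif method == "rag2d":
        feats = [rag2d.structure_features(s) for s in structures]
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = rag2d.rag2d_distance(
                    feats[i], feats[j]
                )
    else:  # aspra
        trees = [aspra.build_structural_tree(s) for s in structures]
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = aspra.align_trees(
                    trees[i], trees[j]
                ).value
    logger.info(
        "%s distances over %d molecules in %.2fs",
        method, n, time.perf_counter() - start,
    )
    return DistanceMatrix(ids=tuple(ids), values=values)


def compute_distance_matrix(folder: Path, method: str) -> DistanceMatrix:
    """Folder of structure files -> dissimilarity matrix."""
    ids, structures = load_structure_folder(Path(folder))
    return distance_matrix_from_structures(ids, structures, method)


def feature_table(
    ids: Sequence[str], structures: Sequence[SecondaryStructure]
) -> pd.DataFrame:
    """Per-molecule RAG-2D feature table with columns id, s, e."""
    rows = []
    for mol_id, s in zip(ids, structures):
        f = rag2d.structure_features(s)
        rows.append({"id": mol_id, "s": f.s, "e": f.e})
    return pd.DataFrame(rows)


def distances_from_features(features: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between (s, e) feature rows."""
    for col in ("id", "s", "e"):
        if col not in features.columns:
            raise PipelineError(f"feature table lacks column {col!r}")
    ids = tuple(str(i) for i in features["id"])
    pts = features[["s", "e"]].to_numpy(dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(ids=ids, values=values)


# ---------------------------------------------------------------------------
# labels and the framework run
# ---------------------------------------------------------------------------

def load_labels(path: Path, rank: str = "phylum") -> Dict[str, str]:
    """Read a labels CSV mapping molecule ID to taxon.

    The file needs an ``id`` column and either the requested rank
    column (e.g. ``phylum``, ``class``, ``order``) or a generic
    ``taxon`` column.
    """
    table = pd.read_csv(path)
    cols = {c.lower(): c for c in table.columns}
    if "id" not in cols:
        raise PipelineError("labels CSV lacks an 'id' column")
    label_col = cols.get(rank.lower()) or cols.get("taxon")
    if label_col is None:
        raise PipelineError(
            f"labels CSV lacks a {rank!r} or 'taxon' column"
        )
    return {
        str(i): str(t) for i, t in zip(table[cols["id"]], table[label_col])
    }


@dataclass(frozen=True)
class RunConfig:
    """One framework invocation (exactly one input mode must be set)."""

    labels_path: Path
    distances_path: Optional[Path] = None
    features_path: Optional[Path] = None
    structures_path: Optional[Path] = None
    method: Optional[str] = None
    linkages: Tuple[str, ...] = LINKAGES
    rank: str = "phylum"
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        modes = [
            self.distances_path is not None,
            self.features_path is not None,
            self.structures_path is not None,
        ]
        if sum(modes) != 1:
            raise PipelineError(
                "exactly one of distances/features/structures input required"
            )
        if self.structures_path is not None and self.method is None:
            raise PipelineError("structures input needs a comparison method")
        unknown = set(self.linkages) - set(LINKAGES)
        if unknown:
            raise PipelineError(f"unknown linkages {sorted(unknown)}")


@dataclass(frozen=True)
class FrameworkResult:
    distance_matrix: DistanceMatrix
    n_clusters: int
    partitions: Dict[str, Dict[str, int]]  # linkage -> id -> cluster
    reports: Dict[str, MetricReport]  # linkage -> metrics

    def report_frame(self) -> pd.DataFrame:
        rows = [
            {"linkage": lk, **rep.as_dict()} for lk, rep in self.reports.items()
        ]
        return pd.DataFrame(rows).set_index("linkage")


def run_framework(config: RunConfig) -> FrameworkResult:
    """Labels + dissimilarity source -> per-linkage metric reports.

    The cluster count equals the number of distinct taxon labels; the
    molecule IDs of the labels file and of the dissimilarity source
    must match one-to-one.
    """
    labels = load_labels(config.labels_path, config.rank)
    if config.distances_path is not None:
        D = DistanceMatrix.from_csv(config.distances_path)
    elif config.features_path is not None:
        D = distances_from_features(pd.read_csv(config.features_path))
    else:
        D = compute_distance_matrix(config.structures_path, config.method)

    if set(D.ids) != set(labels):
        missing = sorted(set(D.ids) ^ set(labels))[:5]
        raise PipelineError(
            f"molecule IDs of labels and distances differ (e.g. {missing})"
        )
    true_labels = [labels[i] for i in D.ids]
    k = num_clusters_from_labels(true_labels)
    logger.info("clustering %d molecules into %d taxa", D.n, k)

    partitions: Dict[str, Dict[str, int]] = {}
    reports: Dict[str, MetricReport] = {}
    for lk in config.linkages:
        _, part = agglomerative_cluster(D, k, lk)
        pred = part.as_list(D.ids)
        partitions[lk] = dict(part.labels)
        reports[lk] = score_partition(true_labels, pred)
    result = FrameworkResult(
        distance_matrix=D, n_clusters=k, partitions=partitions, reports=reports
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.report_frame().to_csv(out / "metrics.csv")
        for lk, assignment in partitions.items():
            pd.DataFrame(
                {"id": list(assignment), "cluster": list(assignment.values())}
            ).to_csv(out / f"clusters_{lk}.csv", index=False)
    return result


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def generate_fixtures(config: GeneratorConfig, out: Path) -> Path:
    """Write a self-contained synthetic input tree under *out*.

    Produces BPSEQ and dot-bracket files for every generated molecule,
    a ``labels.csv`` in the framework's input schema, and a
    ``manifest.json`` recording the metric reports obtained with the
    genus method, for regression testing.
    """
    out = Path(out)
    (out / "bpseq").mkdir(parents=True, exist_ok=True)
    (out / "db").mkdir(parents=True, exist_ok=True)
    ids, taxa, structures = gen_labeled_set(config)
    for mol_id, s in zip(ids, structures):
        (out / "bpseq" / f"{mol_id}.bpseq").write_text(write_bpseq(s))
        (out / "db" / f"{mol_id}.db").write_text(write_dotbracket(s))
    pd.DataFrame({"id": ids, "taxon": taxa}).to_csv(
        out / "labels.csv", index=False
    )
    D = distance_matrix_from_structures(ids, structures, "genus")
    D.to_csv(out / "distances_genus.csv")
    k = num_clusters_from_labels(taxa)
    manifest = {"seed": config.seed, "n_clusters": k, "metrics": {}}
    for lk in LINKAGES:
        _, part = agglomerative_cluster(D, k, lk)
        manifest["metrics"][lk] = score_partition(
            taxa, part.as_list(ids)
        ).as_dict()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
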