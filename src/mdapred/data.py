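"""Containers and file I/O for miRNA-disease association data.

The on-disk dialects are deliberately plain text so that synthetic fixtures
and real exports round-trip identically:

* association lists: two-column TSV, one ``mirna<TAB>disease`` pair per line;
* similarity matrices: square TSV with a header row and an index column of
  node names;
* disease DAG forests: per-disease records introduced by a ``>disease`` header
  line followed by ``child<TAB>parent`` edge lines (a MeSH-like descriptor
  tree flattened to edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "HeterogeneousAdjacency",
    "DiseaseDAG",
    "DiseaseDAGSet",
    "load_associations",
    "save_associations",
    "build_heterogeneous_adjacency",
    "load_disease_dags",
    "save_disease_dags",
    "load_similarity_tsv",
    "save_similarity_tsv",
]


class DataFormatError(ValueError):
    """Raised when an input file violates its dialect."""


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease association matrix with name indices.

    ``values[i, j] == 1`` iff miRNA ``mirna_names[i]`` has a verified
    association with disease ``disease_names[j]``.
    """

    values: np.ndarray
    mirna_names: list[str]
    disease_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if self.values.shape != (len(self.mirna_names), len(self.disease_names)):
            raise ValueError("matrix shape does not match name lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        for names, what in ((self.mirna_names, "miRNA"), (self.disease_names, "disease")):
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate {what} names")

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> np.ndarray:
        """Index pairs (i, j) of known associations, row-major order."""
        return np.argwhere(self.values == 1)

    def masked(self, pairs: np.ndarray) -> "AssociationMatrix":
        """Copy with the given (i, j) pairs zeroed (fold masking)."""
        values = self.values.copy()
        if len(pairs):
            pairs = np.asarray(pairs)
            values[pairs[:, 0], pairs[:, 1]] = 0
        return AssociationMatrix(values, list(self.mirna_names), list(self.disease_names))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirna_names, columns=self.disease_names)


@dataclass
class HeterogeneousAdjacency:
    """Adjacency of the bipartite association network, miRNAs first.

    Block form [[0, A], [A^T, 0]]: node i < nm is miRNA i, node nm + j is
    disease j.
    """

    values: np.ndarray
    n_mirnas: int
    n_diseases: int

    def __post_init__(self) -> None:
        n = self.n_mirnas + self.n_diseases
        if self.values.shape != (n, n):
            raise ValueError("adjacency shape does not match node counts")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("heterogeneous adjacency must be symmetric")
        if self.values[: self.n_mirnas, : self.n_mirnas].any() or self.values[self.n_mirnas :, self.n_mirnas :].any():
            raise ValueError("diagonal blocks must be zero")


def build_heterogeneous_adjacency(assoc: AssociationMatrix) -> HeterogeneousAdjacency:
    """Assemble [[0, A], [A^T, 0]] over miRNA-then-disease node order."""
    nm, nd = assoc.n_mirnas, assoc.n_diseases
    g = np.zeros((nm + nd, nm + nd), dtype=np.int8)
    g[:nm, nm:] = assoc.values
    g[nm:, :nm] = assoc.values.T
    return HeterogeneousAdjacency(g, nm, nd)


def load_associations(path: str | Path) -> AssociationMatrix:
    """Read a two-column TSV of known pairs into a binary matrix.

    Names are whitespace-trimmed and case-sensitive; first-occurrence order
    is preserved; duplicate lines are idempotent.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not all(fields):
                raise DataFormatError(f"{path}:{lineno}: expected 'mirna<TAB>disease', got {line!r}")
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise DataFormatError(f"{path}: no association pairs found")
    mirnas = list(dict.fromkeys(m for m, _ in pairs))
    diseases = list(dict.fromkeys(d for _, d in pairs))
    mi = {m: i for i, m in enumerate(mirnas)}
    di = {d: j for j, d in enumerate(diseases)}
    values = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for m, d in pairs:
        values[mi[m], di[d]] = 1
    return AssociationMatrix(values, mirnas, diseases)


def save_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write known pairs in canonical (lexicographic) order.

    The canonical order makes write -> read -> write byte-stable even though
    loading re-derives name order from first occurrence.
    """
    lines = sorted(
        f"{assoc.mirna_names[i]}\t{assoc.disease_names[j]}\n"
        for i, j in assoc.positive_pairs()
    )
    with open(path, "w") as fh:
        fh.writelines(lines)


@dataclass
class DiseaseDAG:
    """Ancestor closure of one disease with minimal layer depths.

    ``depths[term]`` is the length of the shortest child-to-parent path from
    the disease to ``term``; the disease itself sits at depth 0.
    """

    disease: str
    depths: dict[str, int]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.depths.get(self.disease) != 0:
            raise ValueError(f"disease {self.disease!r} must be at depth 0 of its own DAG")
        if any(d < 0 for d in self.depths.values()):
            raise ValueError("depths must be non-negative")

    @property
    def terms(self) -> set[str]:
        return set(self.depths)


@dataclass
class DiseaseDAGSet:
    """DAGs for a collection of diseases plus global term occurrence counts."""

    dags: dict[str, DiseaseDAG]
    term_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.term_counts:
            self.term_counts = _tally_terms(self.dags)

    @property
    def diseases(self) -> list[str]:
        return list(self.dags)

    @property
    def n_diseases(self) -> int:
        return len(self.dags)


def _tally_terms(dags: Mapping[str, DiseaseDAG]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for dag in dags.values():
        for term in dag.terms:
            counts[term] = counts.get(term, 0) + 1
    return counts


def _closure_from_edges(disease: str, edges: list[tuple[str, str]]) -> DiseaseDAG:
    """Ancestor closure with BFS depths over child->parent edges."""
    g = nx.DiGraph()
    g.add_node(disease)
    g.add_edges_from(edges)
    if disease not in g:
        raise DataFormatError(f"disease {disease!r} absent from its own DAG")
    if not nx.is_directed_acyclic_graph(g):
        raise DataFormatError(f"cycle detected in DAG of disease {disease!r}")
    depths = nx.single_source_shortest_path_length(g, disease)
    return DiseaseDAG(disease, dict(depths), edges=list(edges))


def load_disease_dags(path: str | Path) -> DiseaseDAGSet:
    """Parse the per-disease edge-record dialect into ancestor closures."""
    path = Path(path)
    dags: dict[str, DiseaseDAG] = {}
    disease: str | None = None
    edges: list[tuple[str, str]] = []

    def flush() -> None:
        if disease is not None:
            dags[disease] = _closure_from_edges(disease, edges)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                disease = line[1:].strip()
                if not disease:
                    raise DataFormatError(f"{path}:{lineno}: empty disease header")
                edges = []
            else:
                if disease is None:
                    raise DataFormatError(f"{path}:{lineno}: edge line before any '>' header")
                fields = [f.strip() for f in line.split("\t")]
                if len(fields) != 2 or not all(fields):
                    raise DataFormatError(f"{path}:{lineno}: expected 'child<TAB>parent'")
                edges.append((fields[0], fields[1]))
    flush()
    if not dags:
        raise DataFormatError(f"{path}: no disease records found")
    return DiseaseDAGSet(dags)


def save_disease_dags(dag_set: DiseaseDAGSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for disease, dag in dag_set.dags.items():
            fh.write(f">{disease}\n")
            for child, parent in dag.edges:
                fh.write(f"{child}\t{parent}\n")


def load_similarity_tsv(path: str | Path) -> pd.DataFrame:
    """Square named similarity matrix; index and columns must agree."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise DataFormatError(f"{path}: similarity matrix row/column names differ")
    return df


def save_similarity_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")
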