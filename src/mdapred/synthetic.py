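"""Synthetic miRNA-disease datasets with planted block structure.

The generator emulates the statistical shape the method assumes: a sparse
binary association matrix whose positives concentrate inside matched latent
blocks, similarity views in [0, 1] correlated with the same blocks, and a
small MeSH-like DAG forest whose per-disease ancestor overlap also carries
the block signal.  Everything is deterministic given the seed and is emitted
in exactly the file dialects the loaders consume, so synthetic and real data
travel the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import (
    AssociationMatrix,
    DiseaseDAG,
    DiseaseDAGSet,
    save_associations,
    save_disease_dags,
    save_similarity_tsv,
)
from .similarity import SimilarityView

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "worked_micro_example"]

# similarity of nodes in different blocks, before noise
_BASE_SIMILARITY = 0.2
# sd of the symmetric perturbation added to the block kernel
_VIEW_NOISE_SD = 0.05
# between-block association probability as a fraction of within-block;
# kept at the flip-noise scale so the planted blocks, not the label noise,
# dominate the off-block positives
_CROSS_BLOCK_RATIO = 0.02


@dataclass
class SyntheticSpec:
    """Shape of a generated dataset.

    ``density`` is the expected fraction of positive pairs before label
    noise; ``noise`` flips each entry independently; ``rank`` latent blocks
    are assigned round-robin to both node types.
    """

    nm: int = 60
    nd: int = 60
    rank: int = 4
    density: float = 0.1
    noise: float = 0.02
    dag_depth: int = 3
    dag_branching: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density < 0.5:
            raise ValueError("density must lie in (0, 0.5)")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must lie in [0, 0.5)")
        if self.rank > min(self.nm, self.nd):
            raise ValueError("rank cannot exceed min(nm, nd)")
        if self.rank < 1 or self.dag_depth < 1 or self.dag_branching < 1:
            raise ValueError("rank, dag_depth and dag_branching must be >= 1")


@dataclass
class SyntheticDataset:
    assoc: AssociationMatrix
    mirna_functional: SimilarityView
    disease_semantic: SimilarityView
    dags: DiseaseDAGSet
    mirna_blocks: np.ndarray
    disease_blocks: np.ndarray
    spec: SyntheticSpec

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every component in the standard file dialects."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "associations": out / "associations.tsv",
            "functional": out / "mirna_functional.tsv",
            "semantic": out / "disease_semantic.tsv",
            "dags": out / "disease_dags.txt",
        }
        save_associations(self.assoc, paths["associations"])
        import pandas as pd

        save_similarity_tsv(
            pd.DataFrame(self.mirna_functional.values,
                         index=self.assoc.mirna_names, columns=self.assoc.mirna_names),
            paths["functional"],
        )
        save_similarity_tsv(
            pd.DataFrame(self.disease_semantic.values,
                         index=self.assoc.disease_names, columns=self.assoc.disease_names),
            paths["semantic"],
        )
        save_disease_dags(self.dags, paths["dags"])
        return paths


def _block_view(blocks: np.ndarray, names: list[str], node_type: str, tag: str,
                rng: np.random.Generator) -> SimilarityView:
    same = (blocks[:, None] == blocks[None, :]).astype(float)
    values = np.where(same > 0, 1.0, _BASE_SIMILARITY)
    noise = rng.normal(0.0, _VIEW_NOISE_SD, size=values.shape)
    noise = (noise + noise.T) / 2.0
    values = np.clip(values + noise, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityView(values, names, node_type, tag)


def _block_dag_forest(
    disease_names: list[str], blocks: np.ndarray, spec: SyntheticSpec,
    rng: np.random.Generator
) -> DiseaseDAGSet:
    """Per-disease path to a shared root through block-specific ancestors.

    Each block owns ``dag_branching`` candidate terms per layer; a disease
    follows one sampled term per layer up to the global root and, with some
    probability, attaches an extra first-layer sibling of its own block.
    Diseases of the same block therefore share most ancestors while diseases
    of different blocks share only the root.
    """
    root = "ROOT"
    dags: dict[str, DiseaseDAG] = {}
    for name, b in zip(disease_names, blocks):
        edges: list[tuple[str, str]] = []
        child = name
        for layer in range(1, spec.dag_depth + 1):
            term = f"B{b}_L{layer}_T{rng.integers(spec.dag_branching)}"
            edges.append((child, term))
            child = term
        edges.append((child, root))
        if spec.dag_branching > 1 and rng.random() < 0.3:
            sibling = f"B{b}_L1_T{rng.integers(spec.dag_branching)}"
            if (name, sibling) not in edges:
                edges.append((name, sibling))
        from .data import _closure_from_edges

        dags[name] = _closure_from_edges(name, edges)
    return DiseaseDAGSet(dags)


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Draw one dataset: planted-block associations, views and DAG forest.

    The within-block association probability is calibrated so that the
    expected overall density equals ``spec.density`` before label noise,
    keeping the between/within probability ratio fixed.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    mirna_names = [f"mir-{i:03d}" for i in range(spec.nm)]
    disease_names = [f"disease-{j:03d}" for j in range(spec.nd)]
    block_m = np.arange(spec.nm) % spec.rank
    block_d = np.arange(spec.nd) % spec.rank

    matched = block_m[:, None] == block_d[None, :]
    f_in = matched.mean()
    p_in = spec.density / (f_in + (1 - f_in) * _CROSS_BLOCK_RATIO)
    p_in = min(p_in, 1.0)
    p_out = p_in * _CROSS_BLOCK_RATIO
    probs = np.where(matched, p_in, p_out)
    values = (rng.random(probs.shape) < probs).astype(np.int8)
    if spec.noise > 0:
        flips = rng.random(values.shape) < spec.noise
        values = np.where(flips, 1 - values, values).astype(np.int8)
    assoc = AssociationMatrix(values, mirna_names, disease_names)

    functional = _block_view(block_m, mirna_names, "mirna", "functional", rng)
    semantic = _block_view(block_d, disease_names, "disease", "semantic", rng)
    dags = _block_dag_forest(disease_names, block_d, spec, rng)
    return SyntheticDataset(assoc, functional, semantic, dags, block_m, block_d, spec)


def worked_micro_example() -> SyntheticDataset:
    """Fixed 4-miRNA x 3-disease instance for hand-checkable oracle tests.

    Small enough that the RWR recursion, PPMI entries, attention softmax and
    decoder products can all be verified by explicit enumeration.
    """
    mirnas = ["mir-a", "mir-b", "mir-c", "mir-d"]
    diseases = ["dis-x", "dis-y", "dis-z"]
    values = np.array(
        [
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
            [1, 0, 1],
        ],
        dtype=np.int8,
    )
    assoc = AssociationMatrix(values, mirnas, diseases)
    functional = SimilarityView(
        np.array(
            [
                [1.0, 0.8, 0.1, 0.3],
                [0.8, 1.0, 0.2, 0.1],
                [0.1, 0.2, 1.0, 0.6],
                [0.3, 0.1, 0.6, 1.0],
            ]
        ),
        mirnas,
        "mirna",
        "functional",
    )
    semantic = SimilarityView(
        np.array(
            [
                [1.0, 0.5, 0.2],
                [0.5, 1.0, 0.25],
                [0.2, 0.25, 1.0],
            ]
        ),
        diseases,
        "disease",
        "semantic",
    )
    from .data import _closure_from_edges

    dag_edges = {
        "dis-x": [("dis-x", "t1"), ("t1", "ROOT")],
        "dis-y": [("dis-y", "t1"), ("t1", "ROOT")],
        "dis-z": [("dis-z", "t2"), ("t2", "ROOT")],
    }
    dags = DiseaseDAGSet(
        {d: _closure_from_edges(d, e) for d, e in dag_edges.items()}
    )
    spec = SyntheticSpec(nm=4, nd=3, rank=2, density=0.4, noise=0.0, seed=0)
    return SyntheticDataset(
        assoc, functional, semantic, dags,
        np.array([0, 0, 1, 1]), np.array([0, 0, 1]), spec,
    )
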