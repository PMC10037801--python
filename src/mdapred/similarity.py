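"""The four similarity network views.

Disease semantic similarity (two variants averaged), miRNA functional
similarity (best-match average over associated disease sets), and Gaussian
interaction-profile (GIP) kernel similarity for both node types.  Each view
is a square symmetric matrix in [0, 1] with unit diagonal and serves as one
first-order proximity network for the downstream model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data import AssociationMatrix, DiseaseDAGSet

__all__ = [
    "SimilarityView",
    "semantic_contribution_v1",
    "semantic_contribution_v2",
    "disease_semantic_similarity",
    "average_semantic_views",
    "mirna_functional_similarity",
    "gip_kernel",
    "integrate_views",
]

NodeType = Literal["mirna", "disease"]
ViewTag = Literal["functional", "semantic", "gip", "integrated"]

_SYM_TOL = 1e-8


@dataclass
class SimilarityView:
    """One similarity network: symmetric, unit diagonal, entries in [0, 1]."""

    values: np.ndarray
    node_names: list[str]
    node_type: NodeType
    view_tag: ViewTag

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.node_names)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match node names")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=_SYM_TOL):
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -_SYM_TOL or v.max() > 1 + _SYM_TOL:
            raise ValueError("similarity entries must lie in [0, 1]")
        self.values = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def semantic_contribution_v1(dag, delta: float = 0.5) -> dict[str, float]:
    """Depth-decayed semantic contributions within one disease DAG.

    The disease contributes 1 to itself; an ancestor contributes the maximum
    over paths of delta per edge, i.e. delta ** (minimal layer depth).
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie strictly between 0 and 1")
    if not dag.depths:
        raise ValueError(f"empty DAG for disease {dag.disease!r}")
    return {term: delta**depth for term, depth in dag.depths.items()}


def semantic_contribution_v2(
    terms: set[str], term_counts: dict[str, int], n_diseases: int
) -> dict[str, float]:
    """Frequency-based contributions: -log(count / n_diseases), natural log.

    A term occurring in every disease's DAG contributes 0 (it carries no
    specificity); rarer terms contribute more.
    """
    out: dict[str, float] = {}
    for term in terms:
        count = term_counts.get(term, 0)
        if count < 1:
            raise ValueError(f"term {term!r} has zero DAG count")
        if count > n_diseases:
            raise ValueError(f"term {term!r} count exceeds number of diseases")
        out[term] = -math.log(count / n_diseases)
    return out


def disease_semantic_similarity(
    dags: DiseaseDAGSet, variant: Literal["v1", "v2"] = "v1", delta: float = 0.5
) -> SimilarityView:
    """Pairwise DAG-overlap similarity under one contribution scheme.

    sim(A, B) = sum over shared terms of (D_A(t) + D_B(t)) divided by the
    two total semantic values DV(A) + DV(B).
    """
    diseases = dags.diseases
    contribs: list[dict[str, float]] = []
    for d in diseases:
        dag = dags.dags[d]
        if not dag.depths:
            raise ValueError(f"disease {d!r} has an empty DAG")
        if variant == "v1":
            contribs.append(semantic_contribution_v1(dag, delta))
        elif variant == "v2":
            contribs.append(semantic_contribution_v2(dag.terms, dags.term_counts, dags.n_diseases))
        else:
            raise ValueError(f"unknown variant {variant!r}")
    dv = [sum(c.values()) for c in contribs]
    n = len(diseases)
    sim = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            shared = contribs[a].keys() & contribs[b].keys()
            if not shared or dv[a] + dv[b] == 0:
                continue
            num = sum(contribs[a][t] + contribs[b][t] for t in shared)
            sim[a, b] = sim[b, a] = min(1.0, num / (dv[a] + dv[b]))
    return SimilarityView(sim, diseases, "disease", "semantic")


def average_semantic_views(s1: SimilarityView, s2: SimilarityView) -> SimilarityView:
    """Elementwise mean of the two semantic variants."""
    if s1.values.shape != s2.values.shape or s1.node_names != s2.node_names:
        raise ValueError("semantic views must share shape and node order")
    return SimilarityView((s1.values + s2.values) / 2.0, s1.node_names, "disease", "semantic")


def mirna_functional_similarity(
    assoc: AssociationMatrix, dss: SimilarityView
) -> SimilarityView:
    """Best-match-average functional similarity between miRNAs.

    For disease sets D1, D2 associated with the two miRNAs:
    S = (sum over d in D1 of max_{d' in D2} dss(d, d')
         + sum over d in D2 of max_{d' in D1} dss(d, d')) / (|D1| + |D2|).
    A miRNA with no associated disease is assigned similarity 0 to every
    other miRNA and 1 to itself.
    """
    if dss.node_type != "disease":
        raise ValueError("dss must be a disease view")
    if assoc.disease_names != dss.node_names:
        raise ValueError("association matrix and dss disagree on disease order")
    nm = assoc.n_mirnas
    disease_sets = [np.flatnonzero(assoc.values[i]) for i in range(nm)]
    sim = np.eye(nm)
    for a in range(nm):
        da = disease_sets[a]
        if da.size == 0:
            continue
        # best match of every disease against miRNA a's disease set
        best_vs_a = dss.values[:, da].max(axis=1)
        for b in range(a + 1, nm):
            db = disease_sets[b]
            if db.size == 0:
                continue
            s = dss.values[np.ix_(da, db)].max(axis=1).sum() + best_vs_a[db].sum()
            sim[a, b] = sim[b, a] = min(1.0, s / (da.size + db.size))
    return SimilarityView(sim, assoc.mirna_names, "mirna", "functional")


def gip_kernel(
    profiles: np.ndarray,
    node_names: list[str],
    node_type: NodeType,
    gamma_prime: float = 1.0,
) -> SimilarityView:
    """Gaussian interaction-profile kernel over binary profile rows.

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2) with the bandwidth
    gamma = gamma_prime / mean_i ||IP(i)||^2, so the kernel adapts to the
    overall interaction density.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    profiles = np.asarray(profiles, dtype=float)
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise ValueError("all interaction profiles are zero; GIP bandwidth undefined")
    gamma = gamma_prime / mean_sq
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(sq_dist, 0.0, out=sq_dist)
    return SimilarityView(np.exp(-gamma * sq_dist), node_names, node_type, "gip")


def integrate_views(primary: SimilarityView, filler: SimilarityView) -> SimilarityView:
    """Single integrated view: primary values where non-zero, filler elsewhere.

    This is the construction the integrated-similarity model variant uses in
    place of the two separate views per node type.
    """
    if primary.values.shape != filler.values.shape:
        raise ValueError("views must share shape")
    values = np.where(primary.values > 0, primary.values, filler.values)
    return SimilarityView(values, primary.node_names, primary.node_type, "integrated")
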