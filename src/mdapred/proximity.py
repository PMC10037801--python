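"""Multi-order proximity features: random walk with restart + shifted PPMI.

Each similarity view is row-normalised into a one-step transition matrix,
diffused for K steps of random walk with restart (continuation probability
alpha, restart mass 1 - alpha back to the start node), and each step's
transition matrix is turned into a shifted positive pointwise mutual
information (PPMI) matrix.  Stacking the PPMI matrices of all views and all
steps gives the channel tensor consumed by the convolutional fuser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityView

__all__ = [
    "TransitionSequence",
    "ProximityTensor",
    "row_normalize",
    "rwr_sequence",
    "ppmi",
    "build_proximity_tensor",
]

_STOCHASTIC_TOL = 1e-8


@dataclass
class TransitionSequence:
    """Ordered RWR transition matrices P_1..P_K for one view."""

    matrices: list[np.ndarray]
    alpha: float
    view_tag: str

    def __post_init__(self) -> None:
        for k, p in enumerate(self.matrices, start=1):
            if p.min() < 0:
                raise ValueError(f"P_{k} has negative entries")
            if not np.allclose(p.sum(axis=1), 1.0, atol=_STOCHASTIC_TOL):
                raise ValueError(f"P_{k} is not row-stochastic")


@dataclass
class ProximityTensor:
    """Stacked PPMI channels, view-major then step-minor, for one node type."""

    channels: np.ndarray  # (C_in, n, n)
    node_type: str
    channel_tags: list[tuple[str, int]]  # (view_tag, step)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[1] != self.channels.shape[2]:
            raise ValueError("channels must be a stack of square matrices")
        if len(self.channel_tags) != self.channels.shape[0]:
            raise ValueError("channel tag count mismatch")
        if self.channels.min() < 0:
            raise ValueError("PPMI channels must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.channels.shape[1]

    def save(self, path) -> None:
        """Binary container (npz) with channel metadata."""
        tags = np.array([f"{view}:{step}" for view, step in self.channel_tags])
        np.savez(path, channels=self.channels, node_type=np.array(self.node_type),
                 channel_tags=tags)

    @classmethod
    def load(cls, path) -> "ProximityTensor":
        with np.load(path) as data:
            tags = [
                (t.rsplit(":", 1)[0], int(t.rsplit(":", 1)[1]))
                for t in data["channel_tags"].tolist()
            ]
            return cls(data["channels"], str(data["node_type"]), tags)


def row_normalize(w: np.ndarray) -> np.ndarray:
    """Row-stochastic normalisation of a non-negative square matrix."""
    w = np.asarray(w, dtype=float)
    if w.min() < 0:
        raise ValueError("weight matrix must be non-negative")
    sums = w.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ValueError(f"row(s) {bad.tolist()} sum to zero; cannot normalise")
    return w / sums[:, None]


def rwr_sequence(g_hat: np.ndarray, alpha: float = 0.9, n_steps: int = 3,
                 view_tag: str = "") -> TransitionSequence:
    """K steps of random walk with restart from the identity start.

    P_k = alpha * P_{k-1} @ G_hat + (1 - alpha) * I, which telescopes to the
    closed form alpha^k G_hat^k + (1 - alpha) sum_{t<k} alpha^t G_hat^t.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if n_steps < 1:
        raise ValueError("need at least one RWR step")
    g_hat = np.asarray(g_hat, dtype=float)
    if not np.allclose(g_hat.sum(axis=1), 1.0, atol=_STOCHASTIC_TOL) or g_hat.min() < 0:
        raise ValueError("g_hat must be row-stochastic; apply row_normalize first")
    p0 = np.eye(g_hat.shape[0])
    mats = []
    p = p0
    for _ in range(n_steps):
        p = alpha * (p @ g_hat) + (1 - alpha) * p0
        mats.append(p)
    return TransitionSequence(mats, alpha, view_tag)


def ppmi(p: np.ndarray) -> np.ndarray:
    """Shifted positive PMI of a non-negative matrix, log base 2.

    X_ij = max(0, log2(P_ij * total / (rowsum_i * colsum_j))); cells with
    P_ij = 0 map to 0.  Invariant to global scaling of P.
    """
    p = np.asarray(p, dtype=float)
    if p.min() < 0:
        raise ValueError("PPMI input must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("PPMI input must have positive total mass")
    row = p.sum(axis=1, keepdims=True)
    col = p.sum(axis=0, keepdims=True)
    x = np.zeros_like(p)
    nz = p > 0
    with np.errstate(divide="ignore"):
        x[nz] = np.log2(p[nz] * total / (row @ col)[nz])
    np.maximum(x, 0.0, out=x)
    return x


def build_proximity_tensor(
    views: list[SimilarityView], alpha: float = 0.9, n_steps: int = 3
) -> ProximityTensor:
    """PPMI channels for every (view, step) pair, view-major order."""
    if not views:
        raise ValueError("need at least one view")
    node_type = views[0].node_type
    n = views[0].n
    channels = []
    tags = []
    for view in views:
        if view.node_type != node_type:
            raise ValueError("all views must share a node type")
        if view.n != n:
            raise ValueError("all views must share a shape")
        seq = rwr_sequence(row_normalize(view.values), alpha, n_steps, view.view_tag)
        for k, p in enumerate(seq.matrices, start=1):
            channels.append(ppmi(p))
            tags.append((view.view_tag, k))
    return ProximityTensor(np.stack(channels), node_type, tags)
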