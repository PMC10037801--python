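"""Association prediction model and fitted results.

`MDAModel` is built from an association matrix plus the first-order
similarity views; `fit()` trains the attention network end to end (Adam on
the mean cross-entropy over positive and sampled negative pairs) and returns
an `MDAResults` object carrying the learned parameters, the training
history, the prediction matrix and a `summary()` table.

The model composes, in order: row-normalised RWR diffusion and shifted PPMI
on every similarity view, convolutional fusion of the resulting channel
tensor into a high-order representation, concatenation with the first-order
views, L independent attention heads over the heterogeneous association
network each followed by a two-branch neural aggregator, multi-head
concatenation and a sigmoid inner-product decoder.

Model variants
--------------
``full``
    the complete architecture;
``no_high_order``
    drops the PPMI/convolution block, keeping only first-order views;
``integrated_similarity``
    replaces the two views per node type by a single matrix that takes the
    functional/semantic value where one exists and the GIP value elsewhere;
``plain_gat``
    replaces the neural aggregator by the standard graph-attention output
    (projected to the same width so the decoder shape is unchanged).
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .data import AssociationMatrix, HeterogeneousAdjacency, build_heterogeneous_adjacency
from .proximity import build_proximity_tensor
from .similarity import SimilarityView, integrate_views

__all__ = [
    "ModelConfig",
    "ModelState",
    "MDAModel",
    "MDAResults",
    "sample_negative_pairs",
]

VARIANTS = ("full", "no_high_order", "integrated_similarity", "plain_gat")


@dataclass
class ModelConfig:
    """Hyperparameters of the association model.

    Defaults follow the reference configuration: K = 3 RWR steps, 256
    convolution filters, 256-dimensional transformed features, 2 attention
    heads, learning rate 1e-4, Xavier-normal initialisation and full-batch
    Adam.  ``alpha`` is the RWR continuation probability (restart mass
    1 - alpha); it is not pinned down by the reference configuration and is
    therefore exposed here.
    """

    n_steps: int = 3
    c_out: int = 256
    f_tran: int = 256
    n_heads: int = 2
    learning_rate: float = 1e-4
    epochs: int = 1000
    alpha: float = 0.9
    variant: str = "full"
    leaky_slope: float = 0.2
    activation: str = "elu"
    gamma_prime: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_steps, self.c_out, self.f_tran, self.n_heads, self.epochs) < 1:
            raise ValueError("all size/count hyperparameters must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class ModelState:
    """Trained parameter set plus the configuration that shaped it."""

    params: dict[str, np.ndarray]
    config: ModelConfig

    def hash(self) -> str:
        """SHA-256 over all parameter bytes in sorted key order."""
        h = hashlib.sha256()
        for key in sorted(self.params):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.params[key]).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        """Binary checkpoint (npz) with the config embedded as JSON."""
        arrays = {k: v for k, v in self.params.items()}
        buf = io.BytesIO()
        np.savez(buf, __config__=np.frombuffer(
            json.dumps(self.config.to_dict(), sort_keys=True).encode(), dtype=np.uint8
        ), **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        with np.load(path) as data:
            config = ModelConfig.from_dict(
                json.loads(bytes(data["__config__"].tobytes()).decode())
            )
            params = {k: data[k] for k in data.files if k != "__config__"}
        return cls(params, config)


def sample_negative_pairs(
    assoc_values: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Uniformly sample unknown (zero) pairs, optionally excluding some.

    ``exclude`` is a boolean matrix of additional pairs that must not be
    drawn (e.g. a case-study disease's unknown pairs).
    """
    forbidden = assoc_values.astype(bool)
    if exclude is not None:
        forbidden = forbidden | exclude.astype(bool)
    candidates = np.argwhere(~forbidden)
    if len(candidates) < n_samples:
        raise ValueError(
            f"only {len(candidates)} unknown pairs available, {n_samples} requested"
        )
    idx = rng.choice(len(candidates), size=n_samples, replace=False)
    return candidates[idx]


class MDAModel:
    """miRNA-disease association model over multi-view similarity networks.

    Parameters
    ----------
    assoc
        Training association matrix; its positive entries are the
        supervision signal and its edges define the message-passing graph
        (pass a fold-masked matrix during cross-validation).
    mirna_views, disease_views
        First-order similarity views per node type, typically
        ``[functional, gip]`` and ``[semantic, gip]``.  The GIP views should
        be computed from the same (masked) association matrix.
    config
        Hyperparameters; defaults to ``ModelConfig()``.
    graph
        Optional message-passing adjacency; defaults to the heterogeneous
        adjacency of ``assoc``.
    """

    def __init__(
        self,
        assoc: AssociationMatrix,
        mirna_views: list[SimilarityView],
        disease_views: list[SimilarityView],
        config: ModelConfig | None = None,
        graph: HeterogeneousAdjacency | None = None,
    ) -> None:
        self.assoc = assoc
        self.config = config or ModelConfig()
        if self.config.variant == "integrated_similarity":
            if len(mirna_views) != 2 or len(disease_views) != 2:
                raise ValueError("integrated_similarity needs exactly two views per type")
            mirna_views = [integrate_views(mirna_views[0], mirna_views[1])]
            disease_views = [integrate_views(disease_views[0], disease_views[1])]
        self.mirna_views = mirna_views
        self.disease_views = disease_views
        self.graph = graph or build_heterogeneous_adjacency(assoc)
        self._inputs: dict | None = None

    @property
    def n_mirnas(self) -> int:
        return self.assoc.n_mirnas

    @property
    def n_diseases(self) -> int:
        return self.assoc.n_diseases

    def _build_inputs(self) -> dict:
        """Fixed (non-trainable) forward inputs, cached across fits."""
        if self._inputs is not None:
            return self._inputs
        cfg = self.config
        inputs: dict = {
            "fo_m": np.hstack([v.values for v in self.mirna_views]),
            "fo_d": np.hstack([v.values for v in self.disease_views]),
            "adjacency": self.graph.values.astype(bool),
        }
        if cfg.variant != "no_high_order":
            tensor_m = build_proximity_tensor(self.mirna_views, cfg.alpha, cfg.n_steps)
            tensor_d = build_proximity_tensor(self.disease_views, cfg.alpha, cfg.n_steps)
            inputs["xflat_m"] = nn.flatten_channels(tensor_m.channels)
            inputs["xflat_d"] = nn.flatten_channels(tensor_d.channels)
            inputs["c_in_m"] = tensor_m.n_channels
            inputs["c_in_d"] = tensor_d.n_channels
        else:
            inputs["c_in_m"] = inputs["c_in_d"] = 0
        self._inputs = inputs
        return inputs

    def _default_pairs(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        pos = self.assoc.positive_pairs()
        neg = sample_negative_pairs(self.assoc.values, len(pos), rng)
        pairs = np.vstack([pos, neg])
        labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        return pairs, labels

    def initialize(self, rng: np.random.Generator) -> ModelState:
        inputs = self._build_inputs()
        cfg = self.config
        params = nn.init_params(
            rng,
            self.n_mirnas,
            self.n_diseases,
            inputs["c_in_m"],
            inputs["c_in_d"],
            inputs["fo_m"].shape[1],
            inputs["fo_d"].shape[1],
            cfg.c_out,
            cfg.f_tran,
            cfg.n_heads,
            cfg.variant,
        )
        return ModelState(params, cfg)

    def loss(self, state: ModelState, pairs: np.ndarray, labels: np.ndarray) -> float:
        logits = self._logits(state)
        probs = nn._sigmoid(logits[pairs[:, 0], pairs[:, 1]])
        return nn.bce_loss(probs, labels)

    def _logits(self, state: ModelState) -> np.ndarray:
        cfg = self.config
        return nn.forward(
            state.params, self._build_inputs(), cfg.n_heads, cfg.variant,
            cfg.leaky_slope, cfg.activation,
        )

    def fit(
        self,
        seed: int | None = None,
        train_pairs: np.ndarray | None = None,
        train_labels: np.ndarray | None = None,
        epochs: int | None = None,
    ) -> "MDAResults":
        """Train with full-batch Adam; deterministic given the seed.

        When no explicit training pairs are supplied, all positive entries of
        the association matrix plus an equal number of sampled unknown pairs
        are used, as in the balanced-sampling evaluation protocol.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(seed)
        state = self.initialize(rng)
        if train_pairs is None:
            train_pairs, train_labels = self._default_pairs(rng)
        elif train_labels is None:
            raise ValueError("train_labels required when train_pairs are given")
        pair_idx = (np.asarray(train_pairs)[:, 0], np.asarray(train_pairs)[:, 1])
        inputs = self._build_inputs()
        optimizer = nn.AdamOptimizer(state.params, cfg.learning_rate)
        history = np.empty(epochs)
        for epoch in range(epochs):
            loss, grads = nn.loss_and_grads(
                state.params, inputs, pair_idx, train_labels,
                cfg.n_heads, cfg.variant, cfg.leaky_slope, cfg.activation,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r}; "
                    "consider lowering the learning rate"
                )
            optimizer.step(state.params, grads)
            history[epoch] = loss
        log = pd.DataFrame({"epoch": np.arange(epochs), "loss": history})
        return MDAResults(self, state, log, seed,
                          np.asarray(train_pairs), np.asarray(train_labels))


class MDAResults:
    """Fitted association model: parameters, history, and predictions."""

    def __init__(
        self,
        model: MDAModel,
        state: ModelState,
        history: pd.DataFrame,
        seed: int,
        train_pairs: np.ndarray,
        train_labels: np.ndarray,
    ) -> None:
        self.model = model
        self.state = state
        self.history = history
        self.seed = seed
        self.train_pairs = train_pairs
        self.train_labels = train_labels
        self._scores: np.ndarray | None = None

    @property
    def prediction_matrix(self) -> np.ndarray:
        """Sigmoid inner-product scores for every pair, entries in (0, 1)."""
        if self._scores is None:
            self._scores = nn._sigmoid(self.model._logits(self.state))
        return self._scores

    def predict(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.prediction_matrix,
            index=self.model.assoc.mirna_names,
            columns=self.model.assoc.disease_names,
        )

    def score_pairs(self, pairs: np.ndarray) -> np.ndarray:
        pairs = np.asarray(pairs)
        return self.prediction_matrix[pairs[:, 0], pairs[:, 1]]

    def rank_candidates(
        self, disease: str, exclude_known: bool = True, top_n: int = 20
    ) -> pd.DataFrame:
        """Candidate miRNAs for one disease, ranked by predicted score.

        Ties are broken by stable miRNA order.
        """
        assoc = self.model.assoc
        j = assoc.disease_names.index(disease)
        scores = self.prediction_matrix[:, j]
        candidates = np.arange(assoc.n_mirnas)
        if exclude_known:
            candidates = candidates[assoc.values[:, j] == 0]
        order = candidates[np.argsort(-scores[candidates], kind="stable")][:top_n]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(order) + 1),
                "mirna": [assoc.mirna_names[i] for i in order],
                "score": scores[order],
            }
        )

    @property
    def final_loss(self) -> float:
        return float(self.history["loss"].iloc[-1])

    def summary(self) -> str:
        cfg = self.model.config
        n_params = sum(v.size for v in self.state.params.values())
        lines = [
            "miRNA-disease association model results",
            "=" * 47,
            f"{'variant':<28}{cfg.variant}",
            f"{'miRNAs':<28}{self.model.n_mirnas}",
            f"{'diseases':<28}{self.model.n_diseases}",
            f"{'known associations':<28}{self.model.assoc.n_associations}",
            f"{'RWR steps (K)':<28}{cfg.n_steps}",
            f"{'RWR continuation (alpha)':<28}{cfg.alpha}",
            f"{'conv filters (C_out)':<28}{cfg.c_out}",
            f"{'transformed width (f_tran)':<28}{cfg.f_tran}",
            f"{'attention heads (L)':<28}{cfg.n_heads}",
            f"{'learning rate':<28}{cfg.learning_rate}",
            f"{'epochs':<28}{len(self.history)}",
            f"{'seed':<28}{self.seed}",
            f"{'trainable parameters':<28}{n_params}",
            f"{'training pairs':<28}{len(self.train_pairs)}",
            f"{'initial loss':<28}{self.history['loss'].iloc[0]:.6f}",
            f"{'final loss':<28}{self.final_loss:.6f}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.state.save(path)

    def save_history(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)

    def plot_training(self, ax=None):
        """Loss-versus-epoch curve (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["loss"])
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean cross-entropy")
        ax.set_title("training loss")
        return ax
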