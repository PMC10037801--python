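"""Cross-validation, classification metrics and case-study ranking protocols.

The evaluation protocol is balanced bipartite link prediction: all known
associations are positives, an equal number of unknown pairs is sampled once
as negatives, and the pooled set is split into five folds.  Within each fold
the GIP kernel views and the message-passing graph are recomputed from the
training associations only, so no test edge can leak into training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .data import AssociationMatrix
from .model import MDAModel, ModelConfig, sample_negative_pairs
from .similarity import SimilarityView, gip_kernel

__all__ = [
    "Fold",
    "FoldSpec",
    "MetricsReport",
    "make_folds",
    "fold_views",
    "classification_metrics",
    "tpr_at_k_curve",
    "run_cross_validation",
    "case_study_novel",
    "case_study_new_disease",
]

METRIC_COLUMNS = ["auc", "aupr", "autpr_at_k", "accuracy", "precision", "recall", "f1"]


@dataclass
class Fold:
    """Index pairs (into the association matrix) for one CV round."""

    train_pos: np.ndarray
    test_pos: np.ndarray
    train_neg: np.ndarray
    test_neg: np.ndarray

    def train_set(self) -> tuple[np.ndarray, np.ndarray]:
        pairs = np.vstack([self.train_pos, self.train_neg])
        labels = np.concatenate([np.ones(len(self.train_pos)), np.zeros(len(self.train_neg))])
        return pairs, labels

    def test_set(self) -> tuple[np.ndarray, np.ndarray]:
        pairs = np.vstack([self.test_pos, self.test_neg])
        labels = np.concatenate([np.ones(len(self.test_pos)), np.zeros(len(self.test_neg))])
        return pairs, labels


@dataclass
class FoldSpec:
    folds: list[Fold]
    seed: int

    def __len__(self) -> int:
        return len(self.folds)


def make_folds(assoc: AssociationMatrix, n_folds: int = 5, seed: int = 0) -> FoldSpec:
    """Balanced folds: positives and once-sampled negatives, split jointly.

    All positives and an equal number of sampled unknown pairs are shuffled
    and partitioned into ``n_folds`` near-equal parts, so train and test
    negatives never overlap.
    """
    rng = np.random.default_rng(seed)
    pos = assoc.positive_pairs()
    if len(pos) < n_folds:
        raise ValueError("fewer positives than folds")
    neg = sample_negative_pairs(assoc.values, len(pos), rng)
    pos = pos[rng.permutation(len(pos))]
    neg = neg[rng.permutation(len(neg))]
    pos_parts = np.array_split(pos, n_folds)
    neg_parts = np.array_split(neg, n_folds)
    folds = []
    for f in range(n_folds):
        folds.append(
            Fold(
                train_pos=np.vstack([p for i, p in enumerate(pos_parts) if i != f]),
                test_pos=pos_parts[f],
                train_neg=np.vstack([p for i, p in enumerate(neg_parts) if i != f]),
                test_neg=neg_parts[f],
            )
        )
    return FoldSpec(folds, seed)


def fold_views(
    assoc: AssociationMatrix, fold: Fold, gamma_prime: float = 1.0
) -> tuple[AssociationMatrix, SimilarityView, SimilarityView]:
    """Fold-masked association matrix and its recomputed GIP views.

    Test-positive entries are zeroed before computing the interaction
    profiles, so both the kernels and the message-passing graph derive from
    training edges only.  Semantic and functional views are fold-independent.
    """
    masked = assoc.masked(fold.test_pos)
    if masked.values.sum() == 0:
        raise ValueError("fold masking removed every association; GIP undefined")
    gip_m = gip_kernel(masked.values, masked.mirna_names, "mirna", gamma_prime)
    gip_d = gip_kernel(masked.values.T, masked.disease_names, "disease", gamma_prime)
    return masked, gip_m, gip_d


def classification_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """AUC, AUPR (trapezoidal), AUTPR@k and thresholded Acc/Prec/Recall/F1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("labels contain a single class; AUC undefined")
    auc = skm.roc_auc_score(labels, scores)
    precision, recall, _ = skm.precision_recall_curve(labels, scores)
    aupr = skm.auc(recall, precision)
    predicted = (scores >= threshold).astype(int)
    _, _, autpr = tpr_at_k_curve(scores, labels)
    return {
        "auc": float(auc),
        "aupr": float(aupr),
        "autpr_at_k": autpr,
        "accuracy": float(skm.accuracy_score(labels, predicted)),
        "precision": float(skm.precision_score(labels, predicted, zero_division=0)),
        "recall": float(skm.recall_score(labels, predicted, zero_division=0)),
        "f1": float(skm.f1_score(labels, predicted, zero_division=0)),
    }


def tpr_at_k_curve(
    scores: np.ndarray, labels: np.ndarray, k_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fraction of all positives ranked in the top k, over a grid of k.

    Ties are broken by stable input order.  The area is the trapezoid over
    the curve with an implicit (0, 0) anchor, normalised by n so that it
    lies in [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(scores)
    if k_grid is None:
        k_grid = np.arange(1, n + 1)
    k_grid = np.asarray(k_grid)
    if k_grid.min() < 1 or k_grid.max() > n:
        raise ValueError("k grid must lie within [1, n]")
    order = np.argsort(-scores, kind="stable")
    cum_pos = np.cumsum(labels[order])
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("no positive labels")
    tpr = cum_pos[k_grid - 1] / n_pos
    area = float(np.trapezoid(np.concatenate([[0.0], tpr]), np.concatenate([[0.0], k_grid])) / n)
    return k_grid, tpr, area


@dataclass
class MetricsReport:
    """Per-fold metrics with mean and standard deviation."""

    per_fold: pd.DataFrame
    fold_scores: list[tuple[np.ndarray, np.ndarray]] | None = None

    def mean(self) -> pd.Series:
        return self.per_fold[METRIC_COLUMNS].mean()

    def std(self) -> pd.Series:
        return self.per_fold[METRIC_COLUMNS].std(ddof=1)

    def summary(self) -> str:
        m, s = self.mean(), self.std()
        lines = ["cross-validation metrics (mean +/- sd over folds)", "-" * 49]
        for col in METRIC_COLUMNS:
            lines.append(f"{col:<12}{m[col]:.4f} +/- {s[col]:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        self.per_fold.to_csv(path, index=False)

    def plot_roc(self, ax=None):
        """Per-fold ROC curves from the stored score/label vectors."""
        import matplotlib.pyplot as plt

        if self.fold_scores is None:
            raise ValueError("no stored fold scores to plot")
        if ax is None:
            _, ax = plt.subplots()
        for f, (scores, labels) in enumerate(self.fold_scores):
            fpr, tpr, _ = skm.roc_curve(labels, scores)
            ax.plot(fpr, tpr, label=f"fold {f + 1} (AUC={skm.auc(fpr, tpr):.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=8)
        return ax


def _fold_model(
    assoc: AssociationMatrix,
    fold: Fold,
    mirna_functional: SimilarityView,
    disease_semantic: SimilarityView,
    config: ModelConfig,
) -> tuple[MDAModel, Fold]:
    masked, gip_m, gip_d = fold_views(assoc, fold, config.gamma_prime)
    model = MDAModel(
        masked,
        [mirna_functional, gip_m],
        [disease_semantic, gip_d],
        config,
    )
    return model, fold


def run_cross_validation(
    assoc: AssociationMatrix,
    mirna_functional: SimilarityView,
    disease_semantic: SimilarityView,
    config: ModelConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    folds: FoldSpec | None = None,
    epochs: int | None = None,
) -> MetricsReport:
    """Train one model per fold on masked data and score the held-out pairs.

    A precomputed ``folds`` spec may be passed so that several model variants
    can be compared on identical splits.
    """
    config = config or ModelConfig()
    if folds is None:
        folds = make_folds(assoc, n_folds, seed)
    rng = np.random.default_rng(seed)
    fit_seeds = rng.integers(0, 2**31 - 1, size=len(folds))
    rows = []
    fold_scores = []
    for f, fold in enumerate(folds.folds):
        model, fold = _fold_model(assoc, fold, mirna_functional, disease_semantic, config)
        train_pairs, train_labels = fold.train_set()
        results = model.fit(
            seed=int(fit_seeds[f]), train_pairs=train_pairs, train_labels=train_labels,
            epochs=epochs,
        )
        test_pairs, test_labels = fold.test_set()
        scores = results.score_pairs(test_pairs)
        row = classification_metrics(scores, test_labels)
        row["fold"] = f + 1
        rows.append(row)
        fold_scores.append((scores, test_labels))
    per_fold = pd.DataFrame(rows)[["fold"] + METRIC_COLUMNS]
    return MetricsReport(per_fold, fold_scores)


def case_study_novel(
    assoc: AssociationMatrix,
    mirna_functional: SimilarityView,
    disease_semantic: SimilarityView,
    disease: str,
    config: ModelConfig | None = None,
    seed: int = 0,
    top_n: int = 20,
    epochs: int | None = None,
) -> pd.DataFrame:
    """Rank a disease's unknown miRNA partners after training on all knowns.

    Training uses every known association plus an equal number of unknown
    pairs sampled outside the target disease's column, so none of the ranked
    candidate pairs is seen with a negative label during training.
    """
    config = config or ModelConfig()
    j = assoc.disease_names.index(disease)
    rng = np.random.default_rng(seed)
    pos = assoc.positive_pairs()
    exclude = np.zeros_like(assoc.values, dtype=bool)
    exclude[:, j] = True
    neg = sample_negative_pairs(assoc.values, len(pos), rng, exclude=exclude)
    pairs = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    gip_m = gip_kernel(assoc.values, assoc.mirna_names, "mirna", config.gamma_prime)
    gip_d = gip_kernel(assoc.values.T, assoc.disease_names, "disease", config.gamma_prime)
    model = MDAModel(assoc, [mirna_functional, gip_m], [disease_semantic, gip_d], config)
    results = model.fit(seed=seed, train_pairs=pairs, train_labels=labels, epochs=epochs)
    return results.rank_candidates(disease, exclude_known=True, top_n=top_n)


def case_study_new_disease(
    assoc: AssociationMatrix,
    mirna_functional: SimilarityView,
    disease_semantic: SimilarityView,
    disease: str,
    config: ModelConfig | None = None,
    seed: int = 0,
    top_n: int = 20,
    epochs: int | None = None,
) -> pd.DataFrame:
    """Rank all miRNAs for a disease treated as new (no known partners).

    Every association of the target disease is removed before training (the
    GIP kernels and the message-passing graph are recomputed from the
    reduced matrix) and all of its pairs form the test set.
    """
    config = config or ModelConfig()
    j = assoc.disease_names.index(disease)
    rng = np.random.default_rng(seed)
    disease_pos = np.argwhere(assoc.values[:, j : j + 1] == 1)
    disease_pairs = np.column_stack([disease_pos[:, 0], np.full(len(disease_pos), j)])
    masked = assoc.masked(disease_pairs)
    pos = masked.positive_pairs()
    exclude = np.zeros_like(assoc.values, dtype=bool)
    exclude[:, j] = True
    neg = sample_negative_pairs(masked.values, len(pos), rng, exclude=exclude)
    pairs = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    gip_m = gip_kernel(masked.values, masked.mirna_names, "mirna", config.gamma_prime)
    gip_d = gip_kernel(masked.values.T, masked.disease_names, "disease", config.gamma_prime)
    model = MDAModel(masked, [mirna_functional, gip_m], [disease_semantic, gip_d], config)
    results = model.fit(seed=seed, train_pairs=pairs, train_labels=labels, epochs=epochs)
    return results.rank_candidates(disease, exclude_known=False, top_n=top_n)
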