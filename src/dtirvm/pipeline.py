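"""Interaction-network handling, negative sampling, cross-validated evaluation.

Drug-target interaction data form a bipartite network: drug nodes on one
side, protein target nodes on the other, with edges for experimentally
known interactions.  Known edges are the positive examples; the (much
larger) set of non-edges is the pool of candidate negatives, from which a
balanced negative set is drawn uniformly at random.  Pairs are represented
by the target protein's (PCA-reduced) bi-gram feature vector, optionally
concatenated with a drug descriptor, and evaluated by stratified k-fold
cross-validation with accuracy, sensitivity, precision, Matthews
correlation coefficient, and ROC/AUC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .features import FeatureMatrix, fit_pca, transform_pca
from .rvm import KernelSpec, TrainingConfig, rvm_fit, rvm_predict

METRIC_NAMES = ("Ac", "Sn", "Pe", "Mcc")


@dataclass
class InteractionNetwork:
    """Bipartite drug-target network with a set of known positive edges."""

    drug_ids: List[str]
    target_ids: List[str]
    positive_edges: Set[Tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("duplicate target ids")
        drugs, targets = set(self.drug_ids), set(self.target_ids)
        for d, t in self.positive_edges:
            if d not in drugs or t not in targets:
                raise ValueError(f"edge ({d!r}, {t!r}) references unknown node")

    @classmethod
    def from_pairs_tsv(cls, path: Union[str, Path]) -> "InteractionNetwork":
        """Build a network from a two-column TSV of positive (drug, target) pairs."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["drug_id", "target_id"], dtype=str, comment="#")
        edges = set(zip(df["drug_id"], df["target_id"]))
        return cls(drug_ids=sorted(df["drug_id"].unique()),
                   target_ids=sorted(df["target_id"].unique()),
                   positive_edges=edges)

    def to_pairs_tsv(self, path: Union[str, Path]) -> None:
        with Path(path).open("w") as fh:
            for d, t in sorted(self.positive_edges):
                fh.write(f"{d}\t{t}\n")


@dataclass
class PairDataset:
    """Labelled drug-target pairs aligned with their feature rows."""

    pairs: List[Tuple[str, str, int]]
    X: FeatureMatrix

    def __post_init__(self) -> None:
        if len(self.pairs) != self.X.n_samples:
            raise ValueError("pairs and feature rows misaligned")
        if any(label not in (0, 1) for _, _, label in self.pairs):
            raise ValueError("labels must be 0 or 1")

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, _, label in self.pairs], dtype=int)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Per-fold and aggregate cross-validation metrics plus pooled ROC."""

    per_fold: List[Dict[str, float]]
    mean: Dict[str, float]
    std: Dict[str, float]
    roc: List[Tuple[float, float]]
    auc: float
    config: Dict = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({
            "per_fold": self.per_fold,
            "mean": self.mean,
            "std": self.std,
            "roc": [[float(a), float(b)] for a, b in self.roc],
            "auc": self.auc,
            "config": self.config,
        }, indent=2))

    def roc_to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(self.roc, columns=["FPR", "TPR"]).to_csv(path, index=False)

    def to_table(self) -> str:
        lines = ["fold\t" + "\t".join(METRIC_NAMES)]
        for i, row in enumerate(self.per_fold, start=1):
            lines.append(f"{i}\t" + "\t".join(f"{row[m]:.2f}" for m in METRIC_NAMES))
        lines.append("mean\t" + "\t".join(
            f"{self.mean[m]:.2f}±{self.std[m]:.2f}" for m in METRIC_NAMES))
        lines.append(f"AUC\t{self.auc:.4f}")
        return "\n".join(lines)


def possible_pairs(net: InteractionNetwork) -> int:
    """Total number of drug-target combinations in the bipartite network."""
    return len(net.drug_ids) * len(net.target_ids)


def sample_negatives(net: InteractionNetwork, ratio: float = 1.0,
                     seed: int = 0) -> List[Tuple[str, str]]:
    """Draw non-interacting pairs uniformly without replacement.

    The sample size is round(ratio * number of positive edges); with the
    default ratio of 1 the negative set balances the positives exactly.
    """
    n_drugs, n_targets = len(net.drug_ids), len(net.target_ids)
    total = n_drugs * n_targets
    drug_pos = {d: i for i, d in enumerate(net.drug_ids)}
    target_pos = {t: j for j, t in enumerate(net.target_ids)}
    pos_flat = np.fromiter(
        (drug_pos[d] * n_targets + target_pos[t] for d, t in net.positive_edges),
        dtype=np.int64, count=len(net.positive_edges))
    n_available = total - len(net.positive_edges)
    n_requested = int(round(ratio * len(net.positive_edges)))
    if n_available == 0:
        raise ValueError("network is complete bipartite: no negatives available")
    if n_requested > n_available:
        raise ValueError(
            f"requested {n_requested} negatives but only {n_available} "
            f"non-edges are available")

    mask = np.ones(total, dtype=bool)
    mask[pos_flat] = False
    candidates = np.flatnonzero(mask)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_requested, replace=False)
    return [(net.drug_ids[c // n_targets], net.target_ids[c % n_targets])
            for c in np.sort(chosen)]


def build_pair_dataset(
    net: InteractionNetwork,
    negatives: Sequence[Tuple[str, str]],
    protein_features: Mapping[str, np.ndarray],
    drug_features: Optional[Mapping[str, np.ndarray]] = None,
) -> PairDataset:
    """Assemble the labelled pair feature matrix.

    By default a pair is represented by the target protein's feature vector
    alone; when ``drug_features`` is supplied the pair vector is the
    concatenation drug || protein.
    """
    pairs = [(d, t, 1) for d, t in sorted(net.positive_edges)]
    pairs += [(d, t, 0) for d, t in negatives]

    missing_t = sorted({t for _, t, _ in pairs if t not in protein_features})
    if missing_t:
        raise KeyError(f"missing protein features for targets: {missing_t}")
    if drug_features is not None:
        missing_d = sorted({d for d, _, _ in pairs if d not in drug_features})
        if missing_d:
            raise KeyError(f"missing drug features for drugs: {missing_d}")

    rows = []
    for d, t, _ in pairs:
        vec = np.asarray(protein_features[t], dtype=float).ravel()
        if drug_features is not None:
            vec = np.concatenate([np.asarray(drug_features[d], dtype=float).ravel(),
                                  vec])
        rows.append(vec)
    ids = [f"{d}|{t}" for d, t, _ in pairs]
    return PairDataset(pairs=pairs, X=FeatureMatrix(ids=ids, X=np.vstack(rows)))


def kfold_split(n: int, k: int = 5,
                stratify_labels: Optional[np.ndarray] = None,
                seed: int = 0) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Shuffled (optionally label-stratified) k-fold index partition."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if stratify_labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        it = splitter.split(np.zeros(n), np.asarray(stratify_labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        it = splitter.split(np.zeros(n))
    return [(tr, te) for tr, te in it]


def compute_metrics(c: ConfusionCounts) -> Dict[str, float]:
    """Accuracy, sensitivity (recall), precision and MCC as percentages.

    A metric whose denominator vanishes is reported as NaN.  Sensitivity is
    TP / (TP + FN); MCC uses the standard four-factor denominator and is
    scaled to [-100, 100].
    """
    tp, fp, tn, fn = float(c.TP), float(c.FP), float(c.TN), float(c.FN)
    total = tp + fp + tn + fn
    ac = 100.0 * (tp + tn) / total if total else math.nan
    sn = 100.0 * tp / (tp + fn) if (tp + fn) else math.nan
    pe = 100.0 * tp / (tp + fp) if (tp + fp) else math.nan
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = 100.0 * (tp * tn - fp * fn) / math.sqrt(denom) if denom else math.nan
    return {"Ac": ac, "Sn": sn, "Pe": pe, "Mcc": mcc}


def confusion_from_predictions(y_true: np.ndarray,
                               y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_and_auc(scores: np.ndarray,
                labels: np.ndarray) -> Tuple[List[Tuple[float, float]], float]:
    """ROC points (FPR, TPR) by threshold sweep and trapezoidal AUC."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def aggregate_metrics(per_fold: Sequence[Mapping[str, float]]
                      ) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Mean and sample standard deviation (ddof=1) of each metric over folds."""
    mean, std = {}, {}
    for m in METRIC_NAMES:
        vals = np.array([row[m] for row in per_fold], dtype=float)
        mean[m] = float(np.mean(vals))
        std[m] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, std


def run_cv(dataset: PairDataset, k: int = 5,
           kernel: Optional[KernelSpec] = None,
           cfg: Optional[TrainingConfig] = None,
           pca_components: Optional[int] = 350,
           pca_mode: str = "per_fold",
           seed: int = 0,
           stratify: bool = True) -> MetricsReport:
    """Stratified k-fold cross-validation of the full PCA + RVM pipeline.

    ``pca_mode='per_fold'`` fits PCA on each training fold only (no test
    leakage); ``'global'`` fits once on the pooled data before splitting.
    ``pca_components=None`` skips the reduction (useful when the pair
    features are already low-dimensional).  Scores from all test folds are
    pooled for a single ROC curve and AUC.
    """
    kernel = kernel or KernelSpec()
    cfg = cfg or TrainingConfig()
    if pca_mode not in ("per_fold", "global"):
        raise ValueError("pca_mode must be 'per_fold' or 'global'")
    X = dataset.X.X
    y = dataset.labels
    if pca_components is not None and pca_components >= X.shape[1]:
        raise ValueError(
            f"pca_components={pca_components} must be < feature dimension "
            f"{X.shape[1]} (use None to skip PCA)")

    folds = kfold_split(len(y), k=k,
                        stratify_labels=y if stratify else None, seed=seed)

    global_pca = (fit_pca(X, pca_components)
                  if pca_components is not None and pca_mode == "global" else None)

    per_fold: List[Dict[str, float]] = []
    pooled_scores: List[np.ndarray] = []
    pooled_labels: List[np.ndarray] = []
    for tr, te in folds:
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError("a fold contains a single class; use stratify=True")
        Xtr, Xte = X[tr], X[te]
        if pca_components is not None:
            pca = global_pca if pca_mode == "global" else fit_pca(Xtr, pca_components)
            Xtr, Xte = transform_pca(pca, Xtr), transform_pca(pca, Xte)
        model = rvm_fit(Xtr, y[tr], k=kernel, cfg=cfg)
        scores = rvm_predict(model, Xte)
        preds = (scores >= model.threshold).astype(int)
        per_fold.append(compute_metrics(confusion_from_predictions(y[te], preds)))
        pooled_scores.append(scores)
        pooled_labels.append(y[te])

    mean, std = aggregate_metrics(per_fold)
    roc, auc_value = roc_and_auc(np.concatenate(pooled_scores),
                                 np.concatenate(pooled_labels))
    return MetricsReport(
        per_fold=per_fold, mean=mean, std=std, roc=roc, auc=auc_value,
        config={
            "k": k, "kernel": {"name": kernel.name, "width": kernel.width},
            "init_alpha": cfg.init_alpha, "max_iter": cfg.max_iter,
            "alpha_prune": cfg.alpha_prune, "tol": cfg.tol,
            "pca_components": pca_components, "pca_mode": pca_mode,
            "seed": seed, "stratify": stratify,
        })
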