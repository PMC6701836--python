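"""Fingerprint K-nearest-neighbor classifier with Tanimoto distance.

The ligand-only baseline: each test molecule is scored by the fraction of
actives among its K nearest training fingerprints, K in {1..5} selected by
internal stratified cross-validation on AUC. The score (not just the vote)
is returned so ROC curves are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ..errors import MetricError, TrainingError
from .metrics import roc_auc

logger = logging.getLogger(__name__)


def tanimoto_distance_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto distances ``1 - |x & y| / |x | y|`` between bit-vector
    rows of ``a`` (n x bits) and ``b`` (m x bits).

    Two all-zero vectors are assigned distance 0 (maximally similar), the
    convention used throughout the package.
    """
    a = np.asarray(a, dtype=np.float32)
    b = np.asarray(b, dtype=np.float32)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    sim = np.divide(inter, union, out=np.ones_like(inter), where=union > 0)
    return 1.0 - sim


@dataclass
class KnnModel:
    train_fps: np.ndarray
    train_labels: np.ndarray
    best_k: int
    cv_auc_per_k: dict[int, float]

    def predict(self, fps: np.ndarray, k: int | None = None) -> np.ndarray:
        """Score = fraction of actives among the k nearest training molecules.

        Distance ties are broken by training-set order (stable sort), so
        predictions are deterministic.
        """
        k = self.best_k if k is None else int(k)
        dist = tanimoto_distance_matrix(np.atleast_2d(fps), self.train_fps)
        order = np.argsort(dist, axis=1, kind="stable")[:, :k]
        return self.train_labels[order].mean(axis=1)


def train_knn(
    fingerprints,
    labels,
    k_grid=(1, 2, 3, 4, 5),
    n_folds: int = 5,
    seed: int = 0,
) -> KnnModel:
    """Fit the KNN model, selecting K by stratified cross-validated AUC.

    Ties in mean CV AUC are broken toward smaller K. If a class has fewer
    members than ``n_folds`` the fold count is reduced (down to 2) with a
    logged warning; below that, leave-one-out over the whole set is used.
    """
    fps = np.asarray(fingerprints, dtype=np.uint8)
    y = np.asarray(labels).astype(int).ravel()
    if fps.ndim != 2 or fps.shape[0] != y.size:
        raise TrainingError("fingerprints must be (n, bits) aligned with labels")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise TrainingError("need at least 2 examples per class to cross-validate")

    folds = min(n_folds, int(counts.min()))
    if folds < n_folds:
        logger.warning("reducing CV folds from %d to %d (smallest class has %d members)",
                       n_folds, folds, counts.min())

    cv_scores: dict[int, list[float]] = {int(k): [] for k in k_grid}
    if folds >= 2:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_iter = splitter.split(fps, y)
    else:  # leave-one-out fallback for pathologically tiny sets
        fold_iter = (
            (np.delete(np.arange(y.size), i), np.array([i])) for i in range(y.size)
        )
    dist_full = tanimoto_distance_matrix(fps, fps)
    for train_idx, test_idx in fold_iter:
        sub = dist_full[np.ix_(test_idx, train_idx)]
        order = np.argsort(sub, axis=1, kind="stable")
        for k in k_grid:
            kk = min(int(k), train_idx.size)
            pred = y[train_idx][order[:, :kk]].mean(axis=1)
            try:
                cv_scores[int(k)].append(roc_auc(pred, y[test_idx]))
            except MetricError:
                continue  # single-class fold carries no ranking information
    cv_auc = {
        k: (float(np.mean(v)) if v else 0.5) for k, v in cv_scores.items()
    }
    best_k = min(cv_auc, key=lambda k: (-round(cv_auc[k], 12), k))
    return KnnModel(train_fps=fps, train_labels=y, best_k=int(best_k), cv_auc_per_k=cv_auc)
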