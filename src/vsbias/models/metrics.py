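"""Ranking metrics and their null distributions."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from ..errors import MetricError


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int).ravel()
    if labels.min() == labels.max():
        raise MetricError("AUC requires both classes present")
    return labels


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the probability that a uniformly random active outscores a
    uniformly random decoy, with ties counted half. Labels: 1 = active,
    0 = decoy.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_two_classes(labels)
    if scores.size != labels.size:
        raise MetricError(f"{scores.size} scores vs {labels.size} labels")
    return float(roc_auc_score(labels, scores))


def permutation_null_band(
    scores,
    labels,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided (1 - alpha) null band for AUC under label exchangeability.

    Permutes the labels over the observed scores ``n_permutations`` times and
    returns the (alpha/2, 1 - alpha/2) percentiles of the resulting AUCs —
    the range of AUC values compatible with "no association" for this exact
    test-set size and tie structure.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_two_classes(labels)
    n = scores.size
    n_act = int(labels.sum())
    n_dec = n - n_act
    ranks = rankdata(scores)  # average ranks handle ties -> half-credit
    rng = np.random.default_rng(seed)
    # vectorized: each permutation is a random choice of which ranks are "active"
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n_act]
    rank_sums = ranks[idx].sum(axis=1)
    aucs = (rank_sums - n_act * (n_act + 1) / 2.0) / (n_act * n_dec)
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def pooled_null_band(
    cells,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Null band for a *mean over cells* of AUCs under label exchangeability.

    ``cells`` is a sequence of ``(scores, labels)`` pairs (one per matrix
    cell). Each permutation replicate shuffles every cell's labels
    independently, recomputes each cell AUC from score ranks, and averages;
    the returned band is the (alpha/2, 1-alpha/2) quantile range of those
    pooled means. This is the yardstick for statements like "the
    different-function mean AUC is indistinguishable from chance".
    """
    rng = np.random.default_rng(seed)
    per_cell = []
    for scores, labels in cells:
        scores = np.asarray(scores, dtype=float).ravel()
        labels = _check_two_classes(labels)
        n = scores.size
        n_act = int(labels.sum())
        n_dec = n - n_act
        ranks = rankdata(scores)
        idx = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n_act]
        aucs = (ranks[idx].sum(axis=1) - n_act * (n_act + 1) / 2.0) / (n_act * n_dec)
        per_cell.append(aucs)
    pooled = np.mean(per_cell, axis=0)
    lo, hi = np.quantile(pooled, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def cluster_permutation_null_band(
    cells,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Cluster-exchangeability null band for a mean over cross-target AUC cells.

    Each cell of an actives-as-decoys evaluation compares one *focus*
    target's actives against pooled actives of donor targets. Molecules
    within a target are correlated (they share a chemical-series centroid),
    so permuting molecule labels understates the null variance of the
    pooled mean. Under the null that the scorer is blind to activity, the
    exchangeable units are the clusters themselves: which target plays
    "focus" is arbitrary. Each replicate therefore redraws, per cell, a
    random cluster as the positive class (all its molecules) against the
    remaining clusters, recomputes the cell AUC from score ranks, and
    averages over cells.

    ``cells`` is a sequence of ``(scores, cluster_ids)`` pairs where
    ``cluster_ids`` assigns each score to its source target.
    """
    rng = np.random.default_rng(seed)
    per_cell = []
    for scores, cluster_ids in cells:
        scores = np.asarray(scores, dtype=float).ravel()
        cluster_ids = np.asarray(cluster_ids)
        clusters = np.unique(cluster_ids)
        if clusters.size < 2:
            raise MetricError("cluster permutation needs >= 2 clusters per cell")
        ranks = rankdata(scores)
        n = scores.size
        choices = clusters[rng.integers(0, clusters.size, size=n_permutations)]
        aucs = np.empty(n_permutations)
        masks = {c: cluster_ids == c for c in clusters}
        sums = {c: ranks[masks[c]].sum() for c in clusters}
        sizes = {c: int(masks[c].sum()) for c in clusters}
        for b, c in enumerate(choices):
            n_act = sizes[c]
            n_dec = n - n_act
            aucs[b] = (sums[c] - n_act * (n_act + 1) / 2.0) / (n_act * n_dec)
        per_cell.append(aucs)
    pooled = np.mean(per_cell, axis=0)
    lo, hi = np.quantile(pooled, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def binomial_null_band(n_actives: int, n_decoys: int, alpha: float = 0.05) -> tuple[float, float]:
    """Normal-approximation null band around AUC = 0.5.

    Uses the Mann-Whitney null SD ``sqrt((n_a + n_d + 1) / (12 n_a n_d))``.
    """
    from scipy.stats import norm

    sd = np.sqrt((n_actives + n_decoys + 1) / (12.0 * n_actives * n_decoys))
    z = norm.ppf(1.0 - alpha / 2.0)
    return 0.5 - z * sd, 0.5 + z * sd


def score_correlation(scores_a, scores_b) -> tuple[float, float]:
    """Ordinary least squares of ``scores_b`` on ``scores_a``: (R^2, slope)."""
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.size != b.size:
        raise MetricError("paired score vectors must have equal length")
    if a.size < 3:
        raise MetricError("need at least 3 paired scores")
    var_a = np.var(a)
    if var_a == 0:
        raise MetricError("scores_a is constant; slope undefined")
    slope = float(np.cov(a, b, bias=True)[0, 1] / var_a)
    resid = b - (slope * a + (b.mean() - slope * a.mean()))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return r2, slope
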