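"""Diagnostic battery: what did a screening model actually learn?

Given trained classifiers and controlled test sets, these tools decompose
apparent screening power into its possible sources:

* **receptor ablation** — if test-time removal of all receptor content
  leaves the AUC unchanged, the model never used the receptor;
* **cross-target AUC matrix** — a model trained on one target evaluated on
  every other target's test set; off-diagonal structure reveals information
  that transfers between unrelated proteins;
* **group decomposition** — same-target / similar-function /
  different-function means of that matrix (intra-target analogue bias,
  inter-target analogue bias, decoy bias respectively);
* **actives-as-decoys comparison** — decoy bias disappears on AD test sets,
  so a different-function mean that collapses to chance on AD while staying
  high on default decoys is the signature of decoy bias;
* **distance checks, score summaries, weight profiles, pose sensitivity** —
  supporting forensics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, MetricError
from .models.knn import tanimoto_distance_matrix
from .models.metrics import roc_auc, score_correlation  # noqa: F401  (re-export)
from .records import MoleculeRecord
from .splits import SplitSpec, materialize

#: Gas constant used for the free-energy / inhibition-constant conversion, J/(K mol).
GAS_CONSTANT = 8.31
#: AUC above this counts as "accurately distinguished" in threshold summaries.
HIGH_AUC_THRESHOLD = 0.9
#: A pose-score series whose range is below this fraction of the score scale
#: is flagged pose-insensitive.
FLATNESS_FRACTION = 0.05


# ---------------------------------------------------------------------------
# receptor ablation


@dataclass
class AblationResult:
    auc_with: float
    auc_without: float
    scores_with: np.ndarray
    scores_without: np.ndarray

    @property
    def delta(self) -> float:
        return abs(self.auc_with - self.auc_without)


def ablation_test(model, grids, labels) -> AblationResult:
    """Evaluate a grid model with and without receptor information.

    ``grids`` are voxel grids *with* receptor channels populated; the
    ablated condition zeroes every receptor channel (the dummy-atom
    replacement) before scoring. A delta near zero means the receptor
    content was not used.
    """
    from .featurize import ablate_receptor

    grids = list(grids)
    scores_with = np.asarray(model.predict(grids), dtype=float)
    scores_without = np.asarray(
        model.predict([ablate_receptor(g) for g in grids]), dtype=float
    )
    return AblationResult(
        auc_with=roc_auc(scores_with, labels),
        auc_without=roc_auc(scores_without, labels),
        scores_with=scores_with,
        scores_without=scores_without,
    )


# ---------------------------------------------------------------------------
# cross-target matrix and its decomposition


@dataclass
class AUCMatrix:
    """T x T cross-target AUCs: row = training target, column = test target."""

    values: np.ndarray
    target_ids: list[str]
    families: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        t = len(self.target_ids)
        if self.values.shape != (t, t):
            raise InputError(f"matrix shape {self.values.shape} vs {t} targets")

    def cell(self, model_target: str, test_target: str) -> float:
        i = self.target_ids.index(model_target)
        j = self.target_ids.index(test_target)
        return float(self.values[i, j])

    def high_auc_counts(self, threshold: float = HIGH_AUC_THRESHOLD) -> dict[str, int]:
        """Per test target: number of *other* targets' models exceeding threshold."""
        out = {}
        for j, tid in enumerate(self.target_ids):
            col = np.delete(self.values[:, j], j)
            out[tid] = int(np.nansum(col > threshold))
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.target_ids, columns=self.target_ids)


def cross_target_matrix(
    models: dict[str, "callable"],
    test_splits: dict[str, SplitSpec],
    index: dict[str, MoleculeRecord],
    families: dict[str, str],
    exclude_model_donors: bool = True,
    score_dump: dict | None = None,
) -> AUCMatrix:
    """Evaluate every per-target model on every target's test pool.

    ``models`` maps target_id to a scoring callable ``f(molecules) ->
    scores``; ``test_splits`` maps target_id to the split holding its test
    pool (default-decoy or AD). Entry (i, j) is the AUC of model i on
    target j's test set. Failed cells are recorded as NaN, never fabricated.

    With ``exclude_model_donors`` (default), AD decoys donated by the
    model's own target are dropped from that model's cells: they are the
    model's own (training) actives and would otherwise leak an artificial
    downward bias into every cross-target AD cell at small target counts.

    Pass a dict as ``score_dump`` to receive the per-cell
    ``(mol_ids, scores, labels)`` used for each entry, so every reported
    statistic can be recomputed from dumped scores.
    """
    ids = sorted(models)
    t = len(ids)
    if t < 2:
        raise InputError("cross-target matrix needs at least 2 targets")
    values = np.full((t, t), np.nan)
    for j, tj in enumerate(ids):
        split = test_splits[tj]
        mols, labels = materialize(split, index, tj)
        for i, ti in enumerate(ids):
            keep = np.ones(len(mols), dtype=bool)
            if exclude_model_donors and split.donor_map:
                keep = np.array(
                    [split.donor_map.get(m.mol_id) != ti for m in mols], dtype=bool
                )
            sub = [m for m, k in zip(mols, keep) if k]
            try:
                scores = np.asarray(models[ti](sub), dtype=float)
                values[i, j] = roc_auc(scores, labels[keep])
            except (MetricError, InputError):
                continue  # recorded as missing
            if score_dump is not None:
                score_dump[(ti, tj)] = (
                    [m.mol_id for m in sub], scores, labels[keep].copy()
                )
    return AUCMatrix(values, ids, dict(families))


def group_decompose(matrix: AUCMatrix, family_map: dict[str, str] | None = None) -> dict:
    """Partition the T^2 cells into same-target (diagonal), similar-function
    (off-diagonal, same family) and different-function groups; report the
    mean, population SD and count of each.
    """
    fams = family_map or matrix.families
    for tid in matrix.target_ids:
        if tid not in fams:
            raise InputError(f"target {tid} has no family label")
    groups: dict[str, list[float]] = {"same": [], "similar": [], "different": []}
    for i, ti in enumerate(matrix.target_ids):
        for j, tj in enumerate(matrix.target_ids):
            v = matrix.values[i, j]
            if i == j:
                groups["same"].append(v)
            elif fams[ti] == fams[tj]:
                groups["similar"].append(v)
            else:
                groups["different"].append(v)
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        ok = arr[~np.isnan(arr)]
        out[name] = {
            "mean": float(ok.mean()) if ok.size else float("nan"),
            "sd": float(ok.std()) if ok.size else float("nan"),  # population SD
            "n": int(arr.size),
            "n_missing": int(arr.size - ok.size),
        }
    return out


# ---------------------------------------------------------------------------
# score forensics


def score_distribution_summary(scores, labels) -> dict:
    """Per-class mean +/- population SD of predicted scores."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if labels.min() == labels.max():
        raise MetricError("score summary requires both classes")
    act, dec = scores[labels == 1], scores[labels == 0]
    return {
        "actives": {"mean": float(act.mean()), "sd": float(act.std())},
        "decoys": {"mean": float(dec.mean()), "sd": float(dec.std())},
    }


def weight_profile(model) -> np.ndarray:
    """Mean absolute first-convolutional-layer weight per input channel.

    Shows which input channels a trained grid model attends to; receptor
    channels with profile values far below the ligand channels indicate the
    receptor was effectively ignored during training.
    """
    w = model.first_layer_weights  # (C_in, positions, filters)
    return np.abs(w).mean(axis=(1, 2)).astype(float)


def tanimoto_bias(
    train_mols: list[MoleculeRecord], test_mols: list[MoleculeRecord]
) -> dict[str, float]:
    """Four mean cross-set Tanimoto distances between class pairings.

    Keys: ``train_actives_vs_test_actives``, ``train_decoys_vs_test_actives``,
    ``train_actives_vs_test_decoys``, ``train_decoys_vs_test_decoys``. All
    four being uniformly high (dissimilar) while cross-target AUC stays high
    rules out analogue similarity as the explanation and points to decoy
    bias.
    """
    def split_fp(mols):
        for m in mols:
            if m.fingerprint is None:
                raise InputError(f"molecule {m.mol_id} has no fingerprint")
        act = [m.fingerprint for m in mols if m.is_active]
        dec = [m.fingerprint for m in mols if not m.is_active]
        return act, dec

    tr_a, tr_d = split_fp(train_mols)
    te_a, te_d = split_fp(test_mols)
    out = {}
    for name, a, b in (
        ("train_actives_vs_test_actives", tr_a, te_a),
        ("train_decoys_vs_test_actives", tr_d, te_a),
        ("train_actives_vs_test_decoys", tr_a, te_d),
        ("train_decoys_vs_test_decoys", tr_d, te_d),
    ):
        if not a or not b:
            out[name] = float("nan")
        else:
            out[name] = float(
                tanimoto_distance_matrix(np.stack(a), np.stack(b)).mean()
            )
    return out


@dataclass
class BiasReport:
    """Bundle of audit outputs; any section may be absent for a given run.

    ``group_stats`` holds per-decoy-type group decompositions,
    ``ablation`` per-target with/without/delta AUCs, ``score_summaries``
    per-class score means and SDs, ``correlations`` R^2/slope pairs,
    ``weight_profiles`` per-channel mean |first-layer weight| vectors, and
    ``tanimoto_tables`` the four cross-set mean distances.
    """

    group_stats: dict = field(default_factory=dict)
    ablation: dict = field(default_factory=dict)
    score_summaries: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    weight_profiles: dict = field(default_factory=dict)
    tanimoto_tables: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return [clean(v) for v in obj.tolist()]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return clean(
            {
                "group_stats": self.group_stats,
                "ablation": self.ablation,
                "score_summaries": self.score_summaries,
                "correlations": self.correlations,
                "weight_profiles": self.weight_profiles,
                "tanimoto_tables": self.tanimoto_tables,
                "extras": self.extras,
            }
        )


# ---------------------------------------------------------------------------
# pose sensitivity and affinity conversion


@dataclass
class PoseSeries:
    """(RMSD, score) pairs sorted by RMSD, plus a flatness diagnostic."""

    rmsd: np.ndarray
    scores: np.ndarray
    score_scale: float = 1.0
    extras: dict = field(default_factory=dict)

    @property
    def score_range(self) -> float:
        return float(self.scores.max() - self.scores.min())

    @property
    def flatness_ratio(self) -> float:
        """Score range over score SD; ~0 for a scorer blind to pose quality."""
        sd = float(self.scores.std())
        return self.score_range / sd if sd > 0 else 0.0

    @property
    def insensitive(self) -> bool:
        return self.score_range < FLATNESS_FRACTION * self.score_scale


def pose_sensitivity_curve(scorer, poses, score_scale: float = 1.0) -> PoseSeries:
    """Score a ligand's pose ensemble and order it by pose error.

    ``poses`` is an iterable of ``(rmsd, pose)`` pairs; ``scorer(pose)``
    returns a real score. A scorer whose scores barely move across poses
    from 0 to several Angstrom RMSD (range below 5% of ``score_scale``) is
    flagged insensitive — it is not reading the binding geometry.
    """
    rmsds, scores = [], []
    for rmsd, pose in poses:
        if rmsd < 0:
            raise InputError(f"negative RMSD {rmsd}")
        rmsds.append(float(rmsd))
        scores.append(float(scorer(pose)))
    order = np.argsort(rmsds, kind="stable")
    return PoseSeries(
        rmsd=np.asarray(rmsds)[order],
        scores=np.asarray(scores)[order],
        score_scale=score_scale,
    )


def dg_to_ki(delta_g: float, temperature: float = 298.15) -> float:
    """Inhibition constant (molar) from binding free energy (kJ/mol).

    Inverts ``dG = R T ln(Ki)`` with R = 8.31 J/(K mol); ``delta_g`` is in
    kJ/mol, so a 1 nM binder at 298.15 K corresponds to about -51.3 kJ/mol.
    """
    if temperature <= 0:
        raise InputError("temperature must be positive (K)")
    return float(np.exp(delta_g * 1000.0 / (GAS_CONSTANT * temperature)))


def ki_to_dg(ki: float, temperature: float = 298.15) -> float:
    """Binding free energy (kJ/mol) from an inhibition constant (molar)."""
    if temperature <= 0:
        raise InputError("temperature must be positive (K)")
    if ki <= 0:
        raise InputError("Ki must be positive (molar)")
    return float(GAS_CONSTANT * temperature * np.log(ki) / 1000.0)
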