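"""End-to-end experiments: generate -> featurize -> split -> train -> audit.

The building blocks here are the package's canonical experiments; each is a
plain function returning plain data, reused by the examples, the test suite
and the acceptance script. :func:`run_experiment` wires a preset to disk
artifacts (dataset tables, splits, score dumps, AUC matrices, a JSON bias
report, and a content-hash manifest) so every reported number can be
recomputed from persisted intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import audit
from .errors import ConfigError
from .featurize import GridSpec, add_fingerprints, synthetic_type_map, voxelize
from .models import (
    CnnHyperparams,
    pooled_null_band,
    roc_auc,
    score_correlation,
    train_cnn,
    train_knn,
)
from .models.metrics import permutation_null_band
from .splits import (
    SplitSpec,
    ad_test_split,
    materialize,
    multi_target_split,
    registry,
    single_target_split,
    tiny_split,
)
from .synthgen import BiasConfig, generate_dataset, surrogate_scorer

logger = logging.getLogger(__name__)

PRESETS = (
    "ad-control",
    "receptor-ablation",
    "ligand-vs-receptor",
    "tiny-training",
    "multi-target",
    "pose-toy",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed; documented and stable."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# building blocks


def knn_suite(targets, seed: int, n_bits: int = 2048):
    """One fingerprint-KNN ligand model per target on its single-target split.

    Returns ``(models, splits, index)`` where ``models[tid]`` is a callable
    scoring a list of molecules (by fingerprint) and ``splits[tid]`` the
    split it was trained on.
    """
    add_fingerprints(targets, n_bits)
    index = registry(targets)
    models, splits = {}, {}
    for tgt in targets:
        sp = single_target_split(tgt, seed)
        mols, y = materialize(sp, index)
        fps = np.stack([m.fingerprint for m in mols])
        knn = train_knn(fps, y, seed=seed)
        models[tgt.target_id] = _knn_scorer(knn, n_bits)
        splits[tgt.target_id] = sp
    return models, splits, index


def _knn_scorer(knn, n_bits):
    from .featurize import fingerprint

    def score(mols):
        fps = np.stack([
            m.fingerprint if m.fingerprint is not None and m.fingerprint.size == n_bits
            else fingerprint(m, n_bits)
            for m in mols
        ])
        return knn.predict(fps)

    return score


def ad_suite(targets, splits, scorer=surrogate_scorer, top_n: int = 20, seed: int = 0):
    """Actives-as-decoys test split for every target."""
    return {
        tgt.target_id: ad_test_split(
            tgt, targets, scorer, splits[tgt.target_id], top_n, seed
        )
        for tgt in targets
    }


def cross_target_battery(
    targets,
    seed: int,
    top_n: int = 20,
    with_dumps: bool = False,
):
    """Cross-target AUC matrices and group decompositions on both decoy types.

    Trains one ligand-only KNN per target, evaluates every model on every
    target's default-decoy and AD test sets, and decomposes both matrices
    into same-target / similar-function / different-function groups.
    """
    models, splits, index = knn_suite(targets, seed)
    ad_splits = ad_suite(targets, splits, surrogate_scorer, top_n, seed)
    families = {t.target_id: t.family for t in targets}
    out = {}
    for kind, test_splits in (("default", splits), ("ad", ad_splits)):
        dump: dict = {} if with_dumps else None
        matrix = audit.cross_target_matrix(
            models, test_splits, index, families, score_dump=dump
        )
        out[f"matrix_{kind}"] = matrix
        out[f"groups_{kind}"] = audit.group_decompose(matrix)
        if with_dumps:
            out[f"dumps_{kind}"] = dump
    out["splits"] = splits
    out["ad_splits"] = ad_splits
    out["index"] = index
    return out


def _cell_group(ti: str, tj: str, families: dict) -> str:
    if ti == tj:
        return "same"
    return "similar" if families[ti] == families[tj] else "different"


def group_cells(dumps: dict, families: dict, group: str):
    """Select per-cell (scores, labels) dumps belonging to one group."""
    return [
        (scores, labels)
        for (ti, tj), (_ids, scores, labels) in dumps.items()
        if _cell_group(ti, tj, families) == group
    ]


def group_cluster_cells(dumps: dict, families: dict, group: str, index: dict):
    """Per-cell (scores, source-target ids) for cluster-exchangeability nulls."""
    return [
        ([s for s in scores], [index[m].target_id for m in ids])
        for (ti, tj), (ids, scores, _labels) in dumps.items()
        if _cell_group(ti, tj, families) == group
    ]


def receptor_signal_config(seed: int) -> BiasConfig:
    """Study conditions for the receptor-signal positive control.

    Ten targets whose receptors encode their own actives' topology sign
    pattern (interaction strength 3), no decoy shift, no family sharing,
    cluster spread 0.8: ligand marginals carry no transferable signal, so a
    model can beat chance on held-out targets only by reading the receptor.
    Eight topology slots keep the spatial encoding well separated at the
    reduced grid resolution.
    """
    return BiasConfig(
        n_targets=10, n_families=10, actives_per_target=20, decoys_per_target=20,
        descriptor_dim=16, n_property_dims=8, intra_spread=0.8,
        family_share=0.0, decoy_shift=0.0, interaction_strength=3.0, seed=seed,
    )


def receptor_ablation_experiment(
    seed: int,
    iterations: int = 1000,
    n_train_targets: int = 8,
    config: BiasConfig | None = None,
):
    """Train a receptor+ligand grid CNN where ONLY the receptor carries
    transferable signal; evaluate held-out targets with and without the
    receptor.

    Returns the ablation result, the permutation null band of the held-out
    test set, and the trained model (for weight-profile inspection).
    """
    cfg = config or receptor_signal_config(seed)
    targets = generate_dataset(cfg)
    index = registry(targets)
    by_id = {t.target_id: t for t in targets}
    spec = GridSpec.synthetic()
    tm = synthetic_type_map()
    split = multi_target_split(targets, [t.target_id for t in targets[:n_train_targets]],
                              seed)
    train_mols, train_y = materialize(split, index)
    train_grids = [
        voxelize(by_id[m.target_id].receptor_atoms, m, spec, tm) for m in train_mols
    ]
    test_grids, test_y = [], []
    for tid in sorted(split.test_pools):
        mols, y = materialize(split, index, tid)
        test_grids += [voxelize(by_id[tid].receptor_atoms, m, spec, tm) for m in mols]
        test_y += list(y)
    test_y = np.asarray(test_y)
    model = train_cnn(train_grids, train_y,
                      CnnHyperparams(iterations=iterations, seed=seed))
    result = audit.ablation_test(model, test_grids, test_y)
    band = permutation_null_band(result.scores_without, test_y,
                                 seed=stage_seed(seed, "null"))
    return {
        "ablation": result,
        "null_band": band,
        "model": model,
        "n_test": int(test_y.size),
    }


def ligand_only_cnn_experiment(
    seed: int,
    iterations: int = 400,
    config: BiasConfig | None = None,
):
    """Single-target CNN trained with receptor channels present but no
    receptor-dependent signal (decoy shift only): the ligand-bias regime.

    Returns held-out AUCs with and without test-time receptor ablation, the
    paired score correlation, and the trained model's channel weight
    profile — the forensic trio showing the receptor was ignored.
    """
    cfg = config or BiasConfig(
        n_targets=1, n_families=1, actives_per_target=40, decoys_per_target=200,
        decoy_shift=2.0, family_share=0.0, intra_spread=0.4,
        interaction_strength=3.0, seed=seed,
    )
    targets = generate_dataset(cfg)
    tgt = targets[0]
    index = registry(targets)
    spec = GridSpec.synthetic()
    tm = synthetic_type_map()
    split = single_target_split(tgt, seed)
    train_mols, train_y = materialize(split, index)
    test_mols, test_y = materialize(split, index, tgt.target_id)
    g_train = [voxelize(tgt.receptor_atoms, m, spec, tm) for m in train_mols]
    g_test = [voxelize(tgt.receptor_atoms, m, spec, tm) for m in test_mols]
    model = train_cnn(g_train, train_y, CnnHyperparams(iterations=iterations, seed=seed))
    result = audit.ablation_test(model, g_test, test_y)
    r2, slope = score_correlation(result.scores_with, result.scores_without)
    return {
        "ablation": result,
        "correlation": {"r2": r2, "slope": slope},
        "weight_profile": audit.weight_profile(model),
        "score_summary": audit.score_distribution_summary(result.scores_with, test_y),
        "spec": spec,
        "model": model,
    }


def tiny_training_experiment(
    seed: int,
    n_per_class: int = 5,
    replicates: int = 3,
    iterations: int = 200,
    config: BiasConfig | None = None,
):
    """Replicated 5-active/5-decoy CNN training on one biased target.

    High and stable held-out AUC across replicates indicates actives and
    decoys are so distinguishable that a handful of examples captures the
    separation — a bias fingerprint, not generalizable learning.
    """
    cfg = config or BiasConfig(
        n_targets=1, n_families=1, actives_per_target=40, decoys_per_target=200,
        decoy_shift=2.0, family_share=0.0, intra_spread=0.4, seed=seed,
    )
    tgt = generate_dataset(cfg)[0]
    index = registry([tgt])
    spec = GridSpec.synthetic()
    tm = synthetic_type_map()
    grids_cache: dict[str, object] = {}

    def grids_of(mols):
        out = []
        for m in mols:
            if m.mol_id not in grids_cache:
                grids_cache[m.mol_id] = voxelize(None, m, spec, tm)
            out.append(grids_cache[m.mol_id])
        return out

    aucs = []
    for rep_split in tiny_split(tgt, n_per_class, replicates, seed):
        tr_mols, tr_y = materialize(rep_split, index)
        te_mols, te_y = materialize(rep_split, index, tgt.target_id)
        model = train_cnn(grids_of(tr_mols), tr_y,
                          CnnHyperparams(iterations=iterations, seed=seed))
        aucs.append(roc_auc(model.predict(grids_of(te_mols)), te_y))
    return {"replicate_aucs": aucs,
            "mean": float(np.mean(aucs)), "sd": float(np.std(aucs))}


def multi_target_experiment(
    seed: int,
    n_train_targets: int = 4,
    top_n: int = 20,
    config: BiasConfig | None = None,
):
    """KNN trained on a pooled multi-target training set, tested per
    held-out target on default and AD decoys."""
    cfg = config or BiasConfig(seed=seed)
    targets = generate_dataset(cfg)
    add_fingerprints(targets)
    index = registry(targets)
    split = multi_target_split(targets, [t.target_id for t in targets[:n_train_targets]],
                              seed)
    tr_mols, tr_y = materialize(split, index)
    knn = train_knn(np.stack([m.fingerprint for m in tr_mols]), tr_y, seed=seed)
    scorer = _knn_scorer(knn, 2048)
    held_out = [t for t in targets if t.target_id in split.test_pools]
    default_aucs, ad_aucs = {}, {}
    train_target_ids = {m.target_id for m in tr_mols}
    for tgt in held_out:
        mols, y = materialize(split, index, tgt.target_id)
        default_aucs[tgt.target_id] = roc_auc(scorer(mols), y)
        ad_sp = ad_test_split(tgt, targets, surrogate_scorer,
                              single_target_split(tgt, seed), top_n, seed)
        mols, y = materialize(ad_sp, index, tgt.target_id)
        keep = [i for i, m in enumerate(mols)
                if ad_sp.donor_map.get(m.mol_id) not in train_target_ids]
        mols = [mols[i] for i in keep]
        ad_aucs[tgt.target_id] = roc_auc(scorer(mols), y[keep])
    return {
        "default_aucs": default_aucs,
        "ad_aucs": ad_aucs,
        "default_mean": float(np.mean(list(default_aucs.values()))),
        "ad_mean": float(np.mean(list(ad_aucs.values()))),
    }


def pose_toy_experiment(seed: int, n_poses: int = 100, max_rmsd: float = 6.0):
    """Toy pose-sensitivity study on one synthetic complex.

    Pose ensembles are rigid translations of the crystal pose with RMSD
    spanning 0 to ``max_rmsd`` Angstrom. Two scorers are compared: a
    geometry-aware one (mean receptor-slot contact score, degrades as the
    pose leaves the site) and a pose-blind one (a function of ligand
    composition only), which the flatness diagnostic must flag.
    """
    cfg = BiasConfig(n_targets=1, n_families=1, actives_per_target=2,
                     decoys_per_target=2, interaction_strength=3.0, seed=seed)
    tgt = generate_dataset(cfg)[0]
    mol = tgt.actives[0]
    rng = np.random.default_rng(stage_seed(seed, "poses"))
    poses = []
    for rmsd in np.linspace(0.0, max_rmsd, n_poses):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        poses.append((float(rmsd), mol.atoms.translated(direction * rmsd)))

    rec = tgt.receptor_atoms.coords
    ideal = np.linalg.norm(
        mol.atoms.coords[:, None, :] - rec[None, :, :], axis=2
    ).min(axis=1)  # crystal-pose contact distances

    def contact_scorer(pose):
        d = np.linalg.norm(pose.coords[:, None, :] - rec[None, :, :], axis=2)
        return float(np.exp(-((d.min(axis=1) - ideal) ** 2) / 2.0).mean())

    def blind_scorer(pose):
        return float(len(pose))  # composition only; identical across poses

    sensitive = audit.pose_sensitivity_curve(contact_scorer, poses, score_scale=1.0)
    blind = audit.pose_sensitivity_curve(blind_scorer, poses,
                                         score_scale=float(len(mol.atoms)))
    return {"sensitive": sensitive, "blind": blind}


# ---------------------------------------------------------------------------
# run configuration and orchestration


@dataclass
class RunConfig:
    """Fully serializable description of one experiment run."""

    preset: str = "ad-control"
    seed: int = 0
    out_dir: str = "vsbias_run"
    bias: BiasConfig = field(default_factory=BiasConfig)
    cnn: CnnHyperparams = field(default_factory=CnnHyperparams)
    ad_top_n: int = 20
    n_train_targets: int = 4

    def validate(self) -> "RunConfig":
        if self.preset not in PRESETS:
            raise ConfigError(
                f"preset must be one of {PRESETS}, got {self.preset!r}"
            )
        self.bias.validate()
        return self

    def to_text(self) -> str:
        lines = [f"preset = {self.preset}", f"seed = {self.seed}",
                 f"out_dir = {self.out_dir}", f"ad_top_n = {self.ad_top_n}",
                 f"n_train_targets = {self.n_train_targets}"]
        for f_ in fields(BiasConfig):
            lines.append(f"bias.{f_.name} = {getattr(self.bias, f_.name)}")
        for f_ in fields(CnnHyperparams):
            lines.append(f"cnn.{f_.name} = {getattr(self.cnn, f_.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        flat: dict[str, str] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"malformed config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            flat[key] = value
        kw: dict = {}
        bias_kw: dict = {}
        cnn_kw: dict = {}
        bias_fields = {f_.name: f_.type for f_ in fields(BiasConfig)}
        cnn_fields = {f_.name: f_.type for f_ in fields(CnnHyperparams)}
        for key, value in flat.items():
            if key.startswith("bias."):
                name = key[5:]
                if name not in bias_fields:
                    raise ConfigError(f"unknown config field {key!r}")
                bias_kw[name] = _coerce(value)
            elif key.startswith("cnn."):
                name = key[4:]
                if name not in cnn_fields:
                    raise ConfigError(f"unknown config field {key!r}")
                cnn_kw[name] = _coerce(value)
            elif key in ("preset", "out_dir"):
                kw[key] = value
            elif key in ("seed", "ad_top_n", "n_train_targets"):
                kw[key] = int(value)
            else:
                raise ConfigError(f"unknown config field {key!r}")
        kw["bias"] = BiasConfig(**bias_kw)
        kw["cnn"] = CnnHyperparams(**cnn_kw)
        return cls(**kw).validate()

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def _coerce(value: str):
    if value in ("True", "False"):
        return value == "True"
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        return value


def run_experiment(config: RunConfig) -> audit.BiasReport:
    """Execute a preset end to end and persist its artifacts.

    Writes under ``config.out_dir``: the run config, dataset tables, split
    manifests, per-cell score dumps, AUC matrices, ``bias_report.json`` and
    ``file_manifest.json`` (sha256 of every artifact). Reruns with the same
    config reproduce the hashes. Any stage failure aborts with the stage
    name; artifacts written so far are left for inspection.
    """
    from .io import write_dataset, write_split

    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.txt").write_text(cfg.to_text())
    logger.info("run %s: preset=%s seed=%d config_hash=%s",
                out, cfg.preset, cfg.seed, cfg.config_hash())

    report = audit.BiasReport()
    stage = "setup"

    def _enter(name: str) -> str:
        logger.info("stage %s: seed=%d config_hash=%s", name, cfg.seed,
                    cfg.config_hash())
        return name

    try:
        if cfg.preset == "ad-control":
            stage = _enter("generate")
            targets = generate_dataset(cfg.bias)
            write_dataset(targets, out / "dataset")
            stage = _enter("battery")
            res = cross_target_battery(targets, cfg.seed, cfg.ad_top_n, with_dumps=True)
            stage = _enter("report")
            for kind in ("default", "ad"):
                res[f"matrix_{kind}"].to_frame().to_csv(
                    out / f"auc_matrix_{kind}.tsv", sep="\t"
                )
                report.group_stats[kind] = res[f"groups_{kind}"]
                _dump_scores(out / f"scores_{kind}.tsv", res[f"dumps_{kind}"])
            for tid, sp in res["splits"].items():
                write_split(sp, res["index"], out / f"split_single_{tid}")
            for tid, sp in res["ad_splits"].items():
                write_split(sp, res["index"], out / f"split_ad_{tid}")
            focus = targets[0]
            tr_mols, _ = materialize(res["splits"][focus.target_id], res["index"])
            te_mols, _ = materialize(
                res["splits"][focus.target_id], res["index"], focus.target_id
            )
            report.tanimoto_tables[focus.target_id] = audit.tanimoto_bias(
                tr_mols, te_mols
            )
        elif cfg.preset in ("receptor-ablation",):
            stage = _enter("train")
            res = receptor_ablation_experiment(cfg.seed, cfg.cnn.iterations)
            stage = _enter("report")
            abl = res["ablation"]
            report.ablation["held_out"] = {
                "auc_with": abl.auc_with, "auc_without": abl.auc_without,
                "delta": abl.delta, "null_band": list(res["null_band"]),
            }
            report.weight_profiles["receptor_signal_model"] = audit.weight_profile(
                res["model"]
            )
        elif cfg.preset == "ligand-vs-receptor":
            stage = _enter("train")
            res = ligand_only_cnn_experiment(cfg.seed, cfg.cnn.iterations)
            stage = _enter("report")
            abl = res["ablation"]
            report.ablation["single_target"] = {
                "auc_with": abl.auc_with, "auc_without": abl.auc_without,
                "delta": abl.delta,
            }
            report.correlations["with_vs_without_receptor"] = res["correlation"]
            report.weight_profiles["ligand_bias_model"] = res["weight_profile"]
            report.score_summaries["single_target_test"] = res["score_summary"]
        elif cfg.preset == "tiny-training":
            stage = _enter("train")
            res = tiny_training_experiment(cfg.seed, iterations=cfg.cnn.iterations)
            stage = _enter("report")
            report.extras["tiny_training"] = res
        elif cfg.preset == "multi-target":
            stage = _enter("train")
            res = multi_target_experiment(cfg.seed, cfg.n_train_targets,
                                          cfg.ad_top_n, cfg.bias)
            stage = _enter("report")
            report.extras["multi_target"] = res
        elif cfg.preset == "pose-toy":
            stage = _enter("score")
            res = pose_toy_experiment(cfg.seed)
            stage = _enter("report")
            for name in ("sensitive", "blind"):
                series = res[name]
                report.extras[f"pose_{name}"] = {
                    "rmsd": series.rmsd, "scores": series.scores,
                    "score_range": series.score_range,
                    "flatness_ratio": series.flatness_ratio,
                    "insensitive": bool(series.insensitive),
                }
    except Exception as exc:
        raise RuntimeError(f"experiment stage {stage!r} failed: {exc}") from exc

    (out / "bias_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    _write_file_manifest(out)
    return report


def _dump_scores(path: Path, dumps: dict) -> None:
    import pandas as pd

    rows = []
    for (ti, tj), (ids, scores, labels) in dumps.items():
        for mol_id, s, y in zip(ids, scores, labels):
            rows.append(dict(model_target=ti, test_target=tj, mol_id=mol_id,
                             score=float(s), label=int(y)))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_file_manifest(out: Path) -> None:
    entries = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "file_manifest.json":
            entries[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    (out / "file_manifest.json").write_text(json.dumps(entries, indent=2))
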