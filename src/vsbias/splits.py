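"""Train/test constructions for single-target, multi-target, tiny and
actives-as-decoys (AD) experiments.

The AD construction is the central control: a target's decoys are replaced
by other targets' actives (ranked by a pluggable affinity scorer, top N per
donor), which removes the footprint of the decoy-selection procedure from
the test set. A model whose performance collapses to chance on AD test sets
was riding on decoy bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SplitError
from .records import MoleculeRecord, TargetSet
from .synthgen import _rng

logger = logging.getLogger(__name__)

#: Per-target decoy budget: up to this many decoys are sampled, half train half test.
DECOY_SAMPLE_BUDGET = 1000
#: Decoys per training target in multi-target training pools.
MULTI_TRAIN_DECOY_CAP = 500
#: Actives taken per donor target when building AD decoy sets.
AD_TOP_N = 50


@dataclass
class SplitSpec:
    """A reproducible train/test assignment, by molecule ID.

    ``test_pools`` maps each test target to its molecule IDs (a single-target
    split has one pool). ``donor_map`` records, for AD decoys, which target
    contributed each molecule. ``label_overrides`` marks molecules whose role
    in this split differs from their native label (AD decoys are actives of
    their donor but count as decoys here).
    """

    kind: str
    seed: int
    train_ids: list[str]
    test_pools: dict[str, list[str]]
    donor_map: dict[str, str] = field(default_factory=dict)
    label_overrides: dict[str, str] = field(default_factory=dict)
    decoy_cap: int = DECOY_SAMPLE_BUDGET

    def __post_init__(self) -> None:
        train = set(self.train_ids)
        for target_id, pool in self.test_pools.items():
            overlap = train & set(pool)
            if overlap:
                raise SplitError(
                    f"{len(overlap)} molecules appear in both train and test "
                    f"pool {target_id} (e.g. {sorted(overlap)[0]})"
                )

    @property
    def test_ids(self) -> list[str]:
        return [m for pool in self.test_pools.values() for m in pool]


def registry(targets: list[TargetSet]) -> dict[str, MoleculeRecord]:
    """Index every molecule of a dataset by mol_id."""
    index: dict[str, MoleculeRecord] = {}
    for tgt in targets:
        for mol in tgt.molecules:
            if mol.mol_id in index:
                raise SplitError(f"duplicate mol_id across targets: {mol.mol_id}")
            index[mol.mol_id] = mol
    return index


def materialize(
    spec: SplitSpec, index: dict[str, MoleculeRecord], pool: str | None = None
) -> tuple[list[MoleculeRecord], np.ndarray]:
    """Resolve IDs to records and 0/1 labels (honoring AD label overrides).

    ``pool=None`` resolves the training set; otherwise the named test pool.
    """
    ids = spec.train_ids if pool is None else spec.test_pools[pool]
    mols = [index[i] for i in ids]
    labels = np.array(
        [
            1 if spec.label_overrides.get(m.mol_id, m.label) == "active" else 0
            for m in mols
        ],
        dtype=int,
    )
    return mols, labels


def single_target_split(target: TargetSet, seed: int = 0) -> SplitSpec:
    """Half the actives for training, half for testing; up to 1000 decoys
    sampled and split evenly (train gets the floor on odd counts)."""
    if len(target.actives) < 2 or len(target.decoys) < 2:
        raise SplitError(
            f"target {target.target_id} needs >= 2 actives and >= 2 decoys "
            f"(has {len(target.actives)}/{len(target.decoys)})"
        )
    rng = _rng(seed, 11, _target_key(target))
    act_ids = [m.mol_id for m in target.actives]
    dec_ids = [m.mol_id for m in target.decoys]
    act_perm = list(rng.permutation(act_ids))
    n_train_act = len(act_ids) // 2
    n_dec = min(DECOY_SAMPLE_BUDGET, len(dec_ids))
    dec_sample = list(rng.permutation(dec_ids))[:n_dec]
    n_train_dec = n_dec // 2
    train = act_perm[:n_train_act] + dec_sample[:n_train_dec]
    test = act_perm[n_train_act:] + dec_sample[n_train_dec:]
    return SplitSpec(
        kind="single_target", seed=seed, train_ids=train,
        test_pools={target.target_id: test},
    )


def multi_target_split(
    targets: list[TargetSet], train_target_ids: list[str], seed: int = 0
) -> SplitSpec:
    """Pool half the actives plus up to 500 decoys from each training target;
    build one test pool per held-out target."""
    all_ids = {t.target_id for t in targets}
    train_set = set(train_target_ids)
    if not train_set or not train_set < all_ids:
        raise SplitError(
            "train_target_ids must be a nonempty proper subset of the dataset's targets"
        )
    by_id = {t.target_id: t for t in targets}
    train: list[str] = []
    for tid in sorted(train_set):
        tgt = by_id[tid]
        rng = _rng(seed, 12, _target_key(tgt))
        acts = list(rng.permutation([m.mol_id for m in tgt.actives]))
        decs = list(rng.permutation([m.mol_id for m in tgt.decoys]))
        train += acts[: len(acts) // 2]
        train += decs[: min(MULTI_TRAIN_DECOY_CAP, len(decs))]
    test_pools: dict[str, list[str]] = {}
    for tgt in targets:
        if tgt.target_id in train_set:
            continue
        rng = _rng(seed, 12, _target_key(tgt))
        decs = list(rng.permutation([m.mol_id for m in tgt.decoys]))
        test_pools[tgt.target_id] = [m.mol_id for m in tgt.actives] + decs[
            : min(MULTI_TRAIN_DECOY_CAP, len(decs))
        ]
    return SplitSpec(kind="multi_target", seed=seed, train_ids=train,
                     test_pools=test_pools, decoy_cap=MULTI_TRAIN_DECOY_CAP)


def tiny_split(
    target: TargetSet,
    n_per_class: int = 5,
    replicates: int = 3,
    seed: int = 0,
) -> list[SplitSpec]:
    """Replicated tiny-training experiment: each replicate trains on
    ``n_per_class`` actives + decoys drawn from the single-target training
    half; every replicate shares the same test set."""
    base = single_target_split(target, seed)
    index = registry([target])
    train_act = [i for i in base.train_ids if index[i].is_active]
    train_dec = [i for i in base.train_ids if not index[i].is_active]
    if len(train_act) < n_per_class or len(train_dec) < n_per_class:
        raise SplitError(
            f"training half of {target.target_id} has {len(train_act)} actives / "
            f"{len(train_dec)} decoys; need {n_per_class} of each"
        )
    out = []
    for r in range(replicates):
        rng = _rng(seed, 13, _target_key(target), r)
        picks = list(rng.choice(train_act, size=n_per_class, replace=False)) + list(
            rng.choice(train_dec, size=n_per_class, replace=False)
        )
        out.append(
            SplitSpec(kind="tiny", seed=seed, train_ids=picks,
                      test_pools=dict(base.test_pools))
        )
    return out


def build_ad_decoys(
    focus_target: TargetSet,
    all_targets: list[TargetSet],
    scorer,
    top_n: int = AD_TOP_N,
) -> tuple[list[MoleculeRecord], dict[str, str]]:
    """Actives-as-decoys set for one target.

    Every other target's actives are scored against the focus target by
    ``scorer(molecule, focus_target)``; per donor, the top ``top_n`` by
    descending score (ties broken by mol_id) are taken — all of them when a
    donor has fewer. The union, deduplicated by mol_id, is returned together
    with a mol_id -> donor-target map.
    """
    if len(all_targets) < 2:
        raise SplitError("AD construction needs at least 2 targets")
    selected: list[MoleculeRecord] = []
    donor_map: dict[str, str] = {}
    n_failed = 0
    for donor in all_targets:
        if donor.target_id == focus_target.target_id:
            continue
        scored = []
        for mol in donor.actives:
            try:
                scored.append((scorer(mol, focus_target), mol))
            except Exception:  # noqa: BLE001 - scorer is user-supplied
                n_failed += 1
        scored.sort(key=lambda sm: (-sm[0], sm[1].mol_id))
        for _, mol in scored[: min(top_n, len(scored))]:
            if mol.mol_id in donor_map:  # cross-donor duplicate
                continue
            selected.append(mol)
            donor_map[mol.mol_id] = donor.target_id
    if n_failed:
        logger.warning("AD scorer failed on %d molecules (skipped)", n_failed)
    n_dupes = sum(len(d.actives) for d in all_targets
                  if d.target_id != focus_target.target_id)
    logger.debug("AD set for %s: %d decoys selected (%d donor actives scored)",
                 focus_target.target_id, len(selected), n_dupes)
    return selected, donor_map


def ad_test_split(
    focus_target: TargetSet,
    all_targets: list[TargetSet],
    scorer,
    base_split: SplitSpec | None = None,
    top_n: int = AD_TOP_N,
    seed: int = 0,
) -> SplitSpec:
    """Test split pairing the focus target's test actives with AD decoys.

    The training side is inherited from ``base_split`` (a single-target
    split, built here if not given); only the test pool changes.
    """
    base = base_split or single_target_split(focus_target, seed)
    index = registry([focus_target])
    test_actives = [
        i for i in base.test_pools[focus_target.target_id] if index[i].is_active
    ]
    ad_decoys, donor_map = build_ad_decoys(focus_target, all_targets, scorer, top_n)
    overrides = {m.mol_id: "decoy" for m in ad_decoys}
    return SplitSpec(
        kind="ad_test",
        seed=seed,
        train_ids=list(base.train_ids),
        test_pools={focus_target.target_id: test_actives + [m.mol_id for m in ad_decoys]},
        donor_map=donor_map,
        label_overrides=overrides,
    )


def _target_key(target: TargetSet) -> int:
    """Stable integer key for a target ID (process-independent)."""
    import hashlib

    digest = hashlib.blake2b(target.target_id.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF
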