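"""Diagnostic-battery unit contracts: hand-computed oracles throughout."""

import numpy as np
import pytest

from vsbias import audit
from vsbias.audit import (
    AUCMatrix,
    dg_to_ki,
    group_decompose,
    ki_to_dg,
    pose_sensitivity_curve,
    score_distribution_summary,
    tanimoto_bias,
    weight_profile,
)
from vsbias.errors import InputError, MetricError
from vsbias.records import MoleculeRecord


class TestGroupDecompose:
    def test_hand_partition_3x3(self):
        """Families (A, A, B): 3 same cells, 2 similar, 4 different."""
        values = np.array([[0.9, 0.8, 0.3],
                           [0.7, 0.95, 0.4],
                           [0.2, 0.1, 0.85]])
        m = AUCMatrix(values, ["t1", "t2", "t3"],
                      {"t1": "A", "t2": "A", "t3": "B"})
        g = group_decompose(m)
        assert g["same"]["n"] == 3 and g["similar"]["n"] == 2 and g["different"]["n"] == 4
        assert g["same"]["mean"] == pytest.approx((0.9 + 0.95 + 0.85) / 3)
        assert g["similar"]["mean"] == pytest.approx((0.8 + 0.7) / 2)
        assert g["different"]["mean"] == pytest.approx((0.3 + 0.4 + 0.2 + 0.1) / 4)

    def test_partition_exhaustive_and_disjoint(self):
        t = 5
        m = AUCMatrix(np.full((t, t), 0.5), [f"t{i}" for i in range(t)],
                      {f"t{i}": f"F{i % 2}" for i in range(t)})
        g = group_decompose(m)
        assert g["same"]["n"] + g["similar"]["n"] + g["different"]["n"] == t * t

    def test_constant_matrix(self):
        m = AUCMatrix(np.full((3, 3), 0.7), ["a", "b", "c"],
                      {"a": "F", "b": "F", "c": "G"})
        g = group_decompose(m)
        for name in ("same", "similar", "different"):
            assert g[name]["mean"] == pytest.approx(0.7)
            assert g[name]["sd"] == pytest.approx(0.0)

    def test_unlabeled_target_raises(self):
        m = AUCMatrix(np.eye(2), ["a", "b"], {"a": "F"})
        with pytest.raises(InputError, match="b"):
            group_decompose(m)


def test_high_auc_counts_threshold():
    values = np.array([[0.99, 0.95, 0.2],
                       [0.3, 0.99, 0.4],
                       [0.92, 0.1, 0.99]])
    m = AUCMatrix(values, ["a", "b", "c"], {"a": "F", "b": "F", "c": "G"})
    # per column, count OTHER targets' models above 0.9
    assert m.high_auc_counts(0.9) == {"a": 1, "b": 1, "c": 0}


class TestScoreSummary:
    def test_degenerate_and_hand_values(self):
        s = score_distribution_summary([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        assert s["actives"] == {"mean": 1.0, "sd": 0.0}
        assert s["decoys"] == {"mean": 0.0, "sd": 0.0}
        s = score_distribution_summary([0.8, 1.0, 0.3], [1, 1, 0])
        assert s["actives"]["mean"] == pytest.approx(0.9)
        assert s["actives"]["sd"] == pytest.approx(0.1)  # population SD

    def test_label_swap_swaps_summaries(self, rng):
        scores = rng.random(20)
        labels = (rng.random(20) < 0.5).astype(int)
        labels[:2] = [0, 1]
        a = score_distribution_summary(scores, labels)
        b = score_distribution_summary(scores, 1 - labels)
        assert a["actives"] == b["decoys"] and a["decoys"] == b["actives"]

    def test_single_class_raises(self):
        with pytest.raises(MetricError):
            score_distribution_summary([0.1, 0.2], [1, 1])


class _ToyModel:
    """1-filter first conv layer with hand-set weights."""

    def __init__(self, w):
        self._w = w

    @property
    def first_layer_weights(self):
        return self._w


def test_weight_profile_hand_values():
    w = np.zeros((2, 27, 1))
    assert weight_profile(_ToyModel(w)) == pytest.approx([0.0, 0.0])
    w[0, :, 0] = 1.0
    w[1, 0, 0] = -27.0  # mean |w| = 1 for both channels
    prof = weight_profile(_ToyModel(w))
    assert prof == pytest.approx([1.0, 1.0])
    w[1] = 0.0
    w[1, 0, 0] = -13.5
    assert weight_profile(_ToyModel(w)) == pytest.approx([1.0, 0.5])


class TestTanimotoBias:
    def mk(self, mol_id, label, bits):
        return MoleculeRecord(mol_id=mol_id, target_id="t", label=label,
                              fingerprint=np.array(bits, dtype=np.uint8))

    def test_identical_and_disjoint_sets(self):
        a = [self.mk("a", "active", [1, 1, 0, 0]),
             self.mk("d", "decoy", [0, 0, 1, 1])]
        table = tanimoto_bias(a, a)
        assert table["train_actives_vs_test_actives"] == pytest.approx(0.0)
        assert table["train_decoys_vs_test_decoys"] == pytest.approx(0.0)
        assert table["train_decoys_vs_test_actives"] == pytest.approx(1.0)
        b = [self.mk("a2", "active", [0, 0, 0, 1]),
             self.mk("d2", "decoy", [0, 1, 0, 0])]
        # fully disjoint supports in all four pairings
        disjoint = tanimoto_bias(
            [self.mk("a", "active", [1, 0, 0, 0]),
             self.mk("d", "decoy", [0, 0, 1, 0])], b)
        assert all(v == pytest.approx(1.0) for v in disjoint.values())

    def test_set_arithmetic_example(self):
        table = tanimoto_bias(
            [self.mk("a", "active", [1, 1, 0, 0]),
             self.mk("d", "decoy", [1, 1, 0, 0])],
            [self.mk("a2", "active", [1, 0, 1, 0]),
             self.mk("d2", "decoy", [1, 0, 1, 0])],
        )
        for v in table.values():
            assert v == pytest.approx(2.0 / 3.0)  # sim 1/3

    def test_missing_fingerprint_raises(self):
        bad = MoleculeRecord(mol_id="x", target_id="t", label="active")
        with pytest.raises(InputError):
            tanimoto_bias([bad], [bad])


class TestPoseSensitivity:
    def test_constant_scorer_flagged(self):
        poses = [(float(r), None) for r in range(6)]
        series = pose_sensitivity_curve(lambda pose: 3.3, poses, score_scale=1.0)
        assert series.score_range == 0.0
        assert series.insensitive

    def test_rmsd_scorer_strictly_decreasing(self):
        poses = [(float(r), float(r)) for r in (3, 0, 5, 1, 2)]
        series = pose_sensitivity_curve(lambda pose: -pose, poses, score_scale=5.0)
        assert list(series.rmsd) == [0.0, 1.0, 2.0, 3.0, 5.0]
        assert (np.diff(series.scores) < 0).all()
        assert not series.insensitive

    def test_quadratic_hand_series(self):
        poses = [(r, r) for r in (0.0, 1.0, 2.0, 3.0, 4.0)]
        series = pose_sensitivity_curve(lambda pose: 10 - pose**2, poses,
                                        score_scale=16.0)
        assert list(series.scores) == [10.0, 9.0, 6.0, 1.0, -6.0]

    def test_negative_rmsd_rejected(self):
        with pytest.raises(InputError):
            pose_sensitivity_curve(lambda p: 0.0, [(-1.0, None)])


class TestAffinityConversion:
    def test_unit_ki_zero_energy(self):
        assert ki_to_dg(1.0, 298.15) == 0.0
        assert dg_to_ki(0.0, 298.15) == 1.0

    def test_nanomolar_worked_value(self):
        expected = 8.31 * 298.15 * np.log(1e-9) / 1000.0  # ~ -51.3 kJ/mol
        assert ki_to_dg(1e-9, 298.15) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(-51.34, abs=0.01)

    def test_round_trip(self):
        for x in (1e-12, 1e-9, 1e-3, 0.5):
            assert dg_to_ki(ki_to_dg(x, 310.0), 310.0) == pytest.approx(x, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            dg_to_ki(-50.0, temperature=0.0)
        with pytest.raises(InputError):
            ki_to_dg(-1.0)


def test_cross_target_matrix_hand_recompute(micro_targets):
    """Each matrix cell equals an independently recomputed AUC from the
    dumped per-molecule scores."""
    from vsbias.models import roc_auc
    from vsbias.pipeline import cross_target_battery

    res = cross_target_battery(micro_targets, seed=7, top_n=5, with_dumps=True)
    for kind in ("default", "ad"):
        matrix = res[f"matrix_{kind}"]
        for (ti, tj), (_ids, scores, labels) in res[f"dumps_{kind}"].items():
            assert matrix.cell(ti, tj) == pytest.approx(roc_auc(scores, labels))


def test_weight_profile_flags_unused_receptor_channels(micro_targets, type_map):
    """A CNN trained on grids whose receptor channels are empty (ligand-only
    training) puts less first-layer weight on receptor channels than on
    ligand channels: the profile identifies unused inputs."""
    from vsbias import CnnHyperparams, GridSpec, train_cnn, voxelize

    spec = GridSpec.synthetic(voxels_per_edge=8, resolution=3.0)
    t = micro_targets[0]
    mols = t.actives[:6] + t.decoys[:6]
    labels = np.array([1] * 6 + [0] * 6)
    grids = [voxelize(None, m, spec, type_map) for m in mols]
    model = train_cnn(grids, labels, CnnHyperparams(iterations=80, seed=1))
    prof = weight_profile(model)
    n_rec = spec.n_receptor_channels
    assert prof[:n_rec].mean() < prof[n_rec:].mean()


def test_ablation_identity_zero_receptor_model(micro_targets, type_map):
    from vsbias import CnnHyperparams, GridSpec, train_cnn, voxelize

    spec = GridSpec.synthetic(voxels_per_edge=8, resolution=3.0)
    t = micro_targets[0]
    mols = t.actives[:4] + t.decoys[:4]
    labels = np.array([1] * 4 + [0] * 4)
    grids = [voxelize(t.receptor_atoms, m, spec, type_map) for m in mols]
    model = train_cnn(grids, labels, CnnHyperparams(iterations=10, seed=0))
    w = model.first_layer_weights
    w[: spec.n_receptor_channels] = 0.0
    model.conv_weights[0] = w.reshape(model.conv_weights[0].shape)
    result = audit.ablation_test(model, grids, labels)
    assert result.delta == 0.0
    np.testing.assert_array_equal(result.scores_with, result.scores_without)
    r2, slope = audit.score_correlation(result.scores_with, result.scores_without)
    assert r2 == pytest.approx(1.0) and slope == pytest.approx(1.0)
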