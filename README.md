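# vsbias

Bias audits for structure-based virtual-screening benchmarks.

Benchmark suites for screening models pair each protein target with known
**actives** and property-matched **decoys**. A classifier that ranks actives
above decoys may have learned any mixture of three very different things:

1. **protein–ligand interaction signal** — actual complementarity between a
   ligand and its receptor;
2. **analogue bias** — a target's (or protein family's) actives resemble one
   another, so ligand similarity alone separates the classes;
3. **decoy bias** — the decoy-selection procedure leaves a systematic,
   learnable footprint on the decoys, shared across targets.

Only the first generalizes to new chemistry. `vsbias` provides the
experimental machinery to tell the three apart:

- a **synthetic dataset generator** whose three bias sources are independent
  knobs, so every diagnostic can be validated against ground truth;
- the two classifier families used for such audits: a **3D grid CNN** over
  channelized atom-density voxels (24 Å box, truncated-Gaussian atom
  kernels, three pool→conv→ReLU units and a softmax head, trained by SGD
  with momentum and inverse learning-rate decay) and a **fingerprint KNN**
  (2048-bit fingerprints, Tanimoto distance, K ∈ {1..5} chosen by internal
  cross-validation);
- the **diagnostic battery**: test-time receptor ablation (dummy-atom
  replacement, all receptor channels zeroed), the T×T **cross-target AUC
  matrix**, its decomposition into *same-target / similar-function /
  different-function* groups, the **actives-as-decoys (AD) control** (a
  target's decoys replaced by other targets' actives, which removes decoy
  bias), four-way Tanimoto distance tables, first-layer weight profiles,
  score-distribution summaries, pose-sensitivity curves and the
  ΔG = RT·ln Ki conversion.

Throughout, AUC is the probability that a random active outscores a random
decoy (ties half-credited), and "chance" is made precise by permutation
null bands — label permutation within a test set, and cluster-level
permutation (which target plays "focus" is exchangeable) for pooled
cross-target statistics, where molecules within a target are correlated.

## Worked example

The central control, on a synthetic benchmark with both bias knobs on
(`examples/03_actives_as_decoys_control.py`):

```
group means of the cross-target AUC matrix (KNN ligand-only models):
group                 default decoys   AD decoys
same                     0.990 ± 0.012   0.951 ± 0.030
similar                  0.845 ± 0.109   0.776 ± 0.107
different                0.538 ± 0.144   0.443 ± 0.125
```

Reading: *same-target* AUC ≈ 0.99 — each target's actives are trivially
separable from its decoys by ligand information alone (intra-target
analogue bias). *Similar-function* ≈ 0.85 — models transfer within a
protein family (inter-target analogue bias). *Different-function* ≈ 0.54 on
default decoys — models "work" on unrelated targets, which can only be the
shared decoy footprint; on AD test sets, where that footprint is absent,
the different-function mean collapses to chance. The ordering
same ≥ similar ≥ different holds on both decoy types.

The receptor-ablation controls (`examples/04_receptor_ablation_cnn.py`):

```
negative control (ligand-biased single target, 400 iterations)...
  held-out AUC with receptor 1.000, ablated 1.000, |delta| 0.000
  paired score correlation R^2 0.999, slope 0.968
positive control (receptor-only signal, 8 train / 2 held-out targets, 1000 iterations)...
  held-out AUC with receptor 0.901, ablated 0.514; chance band (0.376, 0.627)
```

A receptor+ligand CNN trained on a ligand-biased target scores identically
with and without the receptor — it never used it. On a dataset where *only*
the receptor carries transferable signal, the same probe collapses a
working model (0.90) to chance (0.51): ablation detects genuine receptor
use when it exists.

Each script in `examples/` is a short narrative: dataset generation and
property matching (01), voxelization and ablation (02), the AD control
(03), CNN ablation (04), pose sensitivity and the affinity conversion (05).
A thin CLI wraps the same pipeline: `vsbias generate`, `vsbias split`,
`vsbias run --preset ad-control`, `vsbias report`.

## Layout

```
src/vsbias/
  synthgen.py    biased-dataset generator, descriptor embedding, surrogate scorer
  featurize.py   voxel grids, receptor ablation, fingerprints, type maps
  models/        grid CNN (numpy), Tanimoto KNN, AUC + null bands
  splits.py      single-target / multi-target / tiny / actives-as-decoys splits
  audit.py       cross-target matrices, group decomposition, ablation tests,
                 Tanimoto tables, pose curves, dG <-> Ki
  pipeline.py    end-to-end experiments and run orchestration
  io.py          TSV dataset manifests, split serialization, PDB/SDF readers
  cli.py         thin command-line wrapper
```

See `docs/methods.md` for the generative model, parameter meanings,
numerical choices and known limitations.
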