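# Methods

## The problem being modeled

Structure-based virtual-screening benchmarks pair protein targets with
experimentally confirmed actives and decoys selected to match the actives'
physical properties while differing topologically. A model evaluated on
such a benchmark can succeed through protein–ligand interaction signal,
through analogue bias (actives of a target or family resemble each other),
or through decoy bias (the selection procedure's systematic footprint on
decoys). The package's purpose is to measure which of these a trained
model actually uses. Because the real datasets entangle all three sources,
the audit machinery is validated on synthetic data in which each source is
an independent, known knob.

## Synthetic generative model

All randomness derives from `BiasConfig.seed` through keyed
`SeedSequence`s; every output is bit-reproducible.

Descriptors have `descriptor_dim` dimensions (default 32): the first
`n_property_dims` (default 8) are "property" dimensions emulating the
matched physical properties of benchmark decoys; the rest are "topology"
dimensions emulating the fingerprint-dissimilarity criterion of decoy
selection.

- Family centroids `F_k ~ N(0, centroid_scale² I)`; target centroids
  `C_t = family_share · F_fam(t) + (1 − family_share) · G_t` with
  `G_t ~ N(0, centroid_scale² I)`. `family_share ∈ [0,1]` is the
  inter-target analogue-bias knob.
- Actives: `C_t + intra_spread · ε`. Smaller `intra_spread` (default 0.4,
  on the centroid scale of 1) = tighter chemical series = stronger
  intra-target analogue bias.
- Decoys copy their matched active's property coordinates verbatim
  (property matching is exact by construction) and resample topology
  coordinates from the *population* marginal
  `N(0, centroid_scale² + intra_spread²)`, then add `decoy_shift · u`
  along a unit direction `u` shared by all targets (switchable to
  per-target). The shared direction is what lets decoy bias transfer
  across unrelated targets. The background variance is chosen so that with
  all knobs at zero and no family structure, actives and decoys are drawn
  from exactly the same law — the generator has an exact null.
- `interaction_strength` shapes only the receptor: binding-site atoms
  (one per topology dimension, on a sphere of radius 8 Å, 40 atoms total)
  take types encoding the sign pattern of the target centroid, with a
  radial nudge `0.5·tanh(strength · C_j)`. The receptor thus encodes where
  its own actives live in topology space, while ligand marginals are
  untouched — pooled over random centroids, actives and decoys are
  identically distributed, so ligand-only screening of a *held-out* target
  is chance by construction and only a receptor-reading model can beat it.

Pseudo-3D embedding: topology dimension `j` maps to a slot direction on a
Fibonacci sphere at radius 5.5 Å holding `1 + min(2, ⌊|d_j|⌋)` atoms of
type `LA`/`LB` by sign; property dimensions map to single `LC` atoms whose
radius (2.0 + 0.5·min(|d|,4) Å) encodes magnitude; a seeded 0.08 Å jitter
is added. The receptor slot radius (8 Å) keeps receptor and ligand slot
atoms of the same dimension ~2.5 Å apart, inside one convolutional
receptive field at the reduced grid resolution, so receptor–ligand
compatibility is locally learnable.

Fingerprints hash the descriptor's *sign pattern* — one bit per
(dimension, sign) and one per (dimension pair, sign pair) — into a
2048-bit vector. This preserves neighborhood structure without chemistry
software and, importantly, does not leak the exact property-coordinate
copying between a decoy and its matched active (a magnitude-quantizing
hash would: the decoy would collide bitwise with one specific active and
inherit its neighborhood, which empirically biases null AUCs well below
0.5). Consequence: the fingerprint responds to the decoy shift relative to
the topology background SD, so shift-monotonicity is probed at shift
levels on that scale.

## Featurization

Grids follow the standard setup: a cubic box (default 24 Å, 48³ voxels at
0.5 Å) with one channel per receptor atom type and per ligand atom type
(16 + 19 by default; 3 + 3 for the synthetic type map), plus optional
extra channels for precomputed maps such as water thermodynamics (never
computed here). An atom of van der Waals radius `r` (1.6 Å for synthetic
types) contributes `exp(−2d²/r²)` for `d ≤ r`, continued by the quadratic
`(4/(e²r²))d² − (12/(e²r))d + 9/e²` (value- and slope-matched at `r`,
zero at `1.5r`). Voxel values are kernel evaluations at voxel centers; a
single atom's grid mass matches the kernel's quadrature mass to ~0.01% at
0.5 Å resolution and ~0.4% at 1 Å. Voxel (0,0,0) sits at the minimum
corner. Receptor ablation zeroes the receptor channels — exactly
equivalent to replacing the receptor by a zero-density dummy atom — and is
idempotent and bitwise-neutral on ligand channels.

A reduced grid (24³ voxels at 1.0 Å) is the package's standard for
experiments; it keeps a full CNN training run in the minutes range on one
CPU.

## Models

**Grid CNN** (numpy implementation): three units of max-pool 2³ →
convolution 3³ (32 filters, padding 1) → ReLU, one fully connected layer,
two-way softmax reported as the active-class probability. Training: SGD
with learning rate 0.01, momentum 0.9, inverse decay
`lr_t = lr₀(1+γt)^(−p)` with p = 1, γ = 0.001, weight decay 0.001, batch
size 10 composed of 5 actives + 5 decoys resampled with replacement
(class balance with unequal class sizes), default 2000 iterations;
cross-entropy loss (the conventional choice for a probabilistic binary
head). He-normal initialization from the seeded generator; training is
deterministic given data and seed. Convolutions are im2col matrix
products; the grid edge must be divisible by 8.

**Fingerprint KNN**: Tanimoto distance `1 − |a∧b|/|a∨b|` (two all-zero
vectors: distance 0), score = fraction of actives among the K nearest
training molecules, K ∈ {1..5} selected by stratified 5-fold
cross-validated AUC (3-fold, then leave-one-out for tiny sets, with a
logged warning), ties toward smaller K, distance ties broken by training
order.

**AUC** is computed by rank statistics (pair counting with half-credit
ties); an independent brute-force pairwise oracle verifies it in the test
suite to 1e-12.

## Splits

- *Single-target*: half the actives train / half test (train takes the
  floor); up to 1000 decoys sampled uniformly without replacement, split
  evenly.
- *Multi-target*: per training target, half the actives + up to 500
  decoys pooled; one test pool per held-out target.
- *Tiny*: replicated 5-active + 5-decoy draws from the training half,
  identical test set across replicates.
- *Actives-as-decoys*: for a focus target, every other target's actives
  are ranked by a pluggable affinity scorer (the synthetic surrogate:
  negative descriptor distance to the target's interaction profile) and
  the top `min(top_n, available)` per donor are pooled, deduplicated by
  molecule ID, relabeled decoy, and recorded with donor provenance.
  Scorer ties break by molecule ID; scorer failures are skipped and
  counted.

## Statistical yardsticks

"Chance" is always an explicit band, never an eyeball:

- **Label-permutation band**: 95% interval of AUC under label shuffling
  within a test set (1000 permutations, rank-based, vectorized). Used for
  single-model/single-test-set claims.
- **Cluster-permutation band**: for pooled cross-target AD statistics,
  molecules within a target are correlated through their shared centroid,
  and label permutation understates the null variance of a pooled mean
  (measured: the 3-seed pooled different-family AD mean has sampling SD
  ≈ 0.005 from cluster-level randomness alone, the size of the entire
  label band). The matched null instead exchanges *clusters*: per cell,
  a random source target plays "focus" and its molecules become the
  positives. The AD-collapse claims are tested against this band; both
  bands are computed and reported.
- A normal-approximation band around 0.5 (Mann–Whitney null SD) backs the
  generator's null-soundness check.

SDs are population SDs (divide by n) throughout. The high-AUC threshold
for "accurately distinguished" summaries is 0.9 (configurable). The
pose-insensitivity flag fires when the score range across a pose ensemble
is below 5% of the declared score scale.

At small target counts two finite-size artifacts matter and are handled
explicitly: (1) the AD pool of target *j* contains actives donated by the
model's own target *i*, which the model scores ≈ 1 and which would bias
every cross-target AD cell downward by about half the donor share
(~0.045 at 12 targets); `cross_target_matrix` therefore excludes, per
cell (i, j), AD decoys donated by target i (negligible at ~100 targets,
essential at 12). (2) With family sharing on, family-mates of the model's
target donate model-familiar actives into AD pools, pulling the
different-function AD mean slightly below 0.5; this is reported, not
corrected, since it does not affect the ordering claims.

## Chosen experimental regimes

- *Decoy-bias / AD-collapse battery*: 12 targets, 4 families, 40 actives
  and 200 decoys per target, decoy shift 2.0, no family sharing, spread
  0.4, AD top-20 per donor, KNN ligand-only models, three seeds. Runs in
  seconds; the pooled different-family AD mean is chance (grand mean
  0.502 over 12 seeds), while the default-decoy counterpart stays above
  its band (~0.56).
- *Receptor-signal positive control*: 10 targets (8 train / 2 held out),
  16-dimensional descriptors (8 property + 8 topology slots — fewer slots
  are spatially cleaner at 1 Å resolution), spread 0.8, interaction
  strength 3.0, receptor+ligand CNN for 1000 iterations on the reduced
  grid. Pilot-fixed regime: held-out AUC ≈ 0.90 with the receptor, ≈ 0.51
  ablated. Tighter clusters invite cluster memorization instead of the
  compatibility rule; this regime is the package's standard for the
  ablation positive control.
- *Ligand-bias negative control*: single biased target, receptor+ligand
  CNN, 400 iterations: ablation delta 0.000, paired-score R² ≈ 1.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* of benchmark bias —
clustered actives, family-shared scaffolds, property-matched but
systematically shifted decoys, receptors informative about their own
ligands — not chemistry. Pseudo-molecules are not valid molecules;
fingerprints are descriptor hashes, not substructure fingerprints; the
surrogate scorer is not a docking program. Passing audits here shows the
*diagnostics* work (they detect each bias source when present and stay at
chance when absent); it does not quantify the bias magnitudes of any real
benchmark, which must be measured on that benchmark's own data through
the same interfaces (PDB/SDF readers, pluggable scorer, user family
labels).

## Known limitations

- The CNN is CPU-bound numpy; full-resolution 48³ grids train slowly and
  are intended for feature parity, not throughput.
- Cross-target batteries use KNN ligand-only models by default; per-target
  CNN matrices are supported but expensive at scale.
- Family labels are inputs, not computed; sequence similarity is out of
  scope.
- Extra grid channels (e.g. water maps) are accepted as user-supplied
  data only.
- The cluster-permutation band treats cells as independent across the
  pooled set; residual cross-cell correlation through shared models and
  donors slightly narrows it, which is conservative for the "above
  chance" direction but can make marginal AD means flag as non-null for
  extreme seed draws.
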