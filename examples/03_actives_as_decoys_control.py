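"""The actives-as-decoys (AD) control: separating decoy bias from analogue bias.

Trains one ligand-only fingerprint-KNN per target, evaluates every model on
every target's test set (default decoys and AD decoys), and decomposes both
cross-target AUC matrices into same-target / similar-function /
different-function groups. The signature of decoy bias: different-function
AUC above chance on default decoys but at chance on AD test sets.
"""

import numpy as np

from vsbias import BiasConfig, generate_dataset
from vsbias.pipeline import cross_target_battery

config = BiasConfig(
    n_targets=12, n_families=4, actives_per_target=40, decoys_per_target=200,
    decoy_shift=2.0, family_share=0.5, intra_spread=0.4, seed=1,
)
res = cross_target_battery(generate_dataset(config), seed=1, top_n=20)

print("group means of the cross-target AUC matrix (KNN ligand-only models):")
print(f"{'group':<20}{'default decoys':>16}{'AD decoys':>12}")
for group in ("same", "similar", "different"):
    d = res["groups_default"][group]
    a = res["groups_ad"][group]
    print(f"{group:<20}{d['mean']:>10.3f} ± {d['sd']:.3f}"
          f"{a['mean']:>8.3f} ± {a['sd']:.3f}")

n_high = res["matrix_default"].high_auc_counts(0.9)
print(f"\ntargets separable (AUC>0.9) by at least one OTHER target's model "
      f"(default decoys): {sum(1 for v in n_high.values() if v > 0)}"
      f"/{len(n_high)}")
print("-> same >= similar >= different on both decoy types, and the "
      "different-function mean collapses to (here slightly below) chance on "
      "AD sets: what transferred between unrelated targets was decoy bias, "
      "not chemistry. (The dip below 0.5 is family-mates of the training "
      "target donating model-familiar actives into the AD pools — amplified "
      "at 12 targets relative to a 100-target benchmark.)")
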