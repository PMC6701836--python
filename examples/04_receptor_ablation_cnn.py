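"""Receptor ablation on a grid CNN: a positive and a negative control.

Negative control: a single-target CNN trained on receptor+ligand grids of a
ligand-biased dataset — ablating the receptor at test time changes nothing,
because the ligand channels already separate actives from decoys.

Positive control: a multi-target CNN trained where ONLY the receptor
carries transferable signal (receptors encode their actives' topology
pattern) — it beats chance on held-out targets, and ablation collapses it
to chance. The probe detects genuine receptor use when it exists.

Runtime: a few minutes on one CPU (two small CNN trainings).
"""

from vsbias.pipeline import ligand_only_cnn_experiment, receptor_ablation_experiment

print("negative control (ligand-biased single target, 400 iterations)...")
res = ligand_only_cnn_experiment(seed=1, iterations=400)
abl = res["ablation"]
print(f"  held-out AUC with receptor {abl.auc_with:.3f}, ablated "
      f"{abl.auc_without:.3f}, |delta| {abl.delta:.3f}")
print(f"  paired score correlation R^2 {res['correlation']['r2']:.3f}, "
      f"slope {res['correlation']['slope']:.3f}")
prof = res["weight_profile"]
print(f"  mean |first-layer weight|: receptor channels {prof[:3].mean():.4f}, "
      f"ligand channels {prof[3:].mean():.4f}")
print("  -> tiny delta, R^2 ~ 1: the receptor was ignored.")

print("\npositive control (receptor-only signal, 8 train / 2 held-out targets,"
      " 1000 iterations)...")
res = receptor_ablation_experiment(seed=1, iterations=1000)
abl = res["ablation"]
lo, hi = res["null_band"]
print(f"  held-out AUC with receptor {abl.auc_with:.3f}, ablated "
      f"{abl.auc_without:.3f}; chance band ({lo:.3f}, {hi:.3f})")
print("  -> above-chance performance disappears under ablation: this model "
      "really was reading the receptor.")
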