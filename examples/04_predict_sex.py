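"""Classify donor sex from immune features with module-structured penalties.

Trains ridge, lasso, group lasso, and sparse group lasso logistic models
(groups = detected modules) on 50 donors and evaluates on the remaining 36,
plus a lasso on per-donor module scores.
"""

from cytomodules import (PipelineConfig, run_pipeline, sex_shift_config)

config = PipelineConfig(sim=sex_shift_config(seed=2), run_stats=False, seed=2)
result = run_pipeline(config)

print(f"{result.features.data.shape[1]} features, "
      f"{len(result.assignment.module_ids)} modules, "
      "50 train / 36 test donors\n")
print(f"{'model':24s} {'accuracy':>8s} {'AUC':>6s} {'selected':>9s}")
for name, r in result.model_results.items():
    ev = r["evaluation"]
    print(f"{name:24s} {ev['accuracy']:8.2f} {ev['auc']:6.2f} "
          f"{len(r['fit'].selected):9d}")
sel = result.model_results["module_score_lasso"]["selected_modules"]
print(f"\nmodule-score lasso selected modules: {sel}")
# Accuracy is the fraction of held-out donors classified correctly at
# p = 0.5; AUC is threshold-free ranking quality (0.5 = chance).  The
# group-aware penalties exploit that informative features arrive in
# whole signaling-protein modules.
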