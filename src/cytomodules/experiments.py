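"""Reproducibility experiments: planted-structure recovery and calibration.

Each function runs one self-contained experiment on synthetic cohorts at the
package's study conditions and returns plain dictionaries of measured
quantities.  They back both the acceptance checks and the replication
script, so the numbers those report are always recomputed from scratch.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import models as mdl
from .config import ModelConfig, PipelineConfig
from .features import featurize_cohort, threshold_features
from .modules import (ModuleAssignment, bin_adjacency, cluster_features,
                      correlation_matrix, extract_modules, module_summary,
                      within_module_correlation)
from .pipeline import fit_sex_classifiers
from .sam import sam_permutation_fdr, significant_features
from .simulate import (SimConfig, generate_cohort, sex_coordination_config,
                       sex_shift_config, truth_modules,
                       SEX_SHIFT_FEMALE_PROTEINS, SEX_SHIFT_MALE_PROTEINS)
from .stats import (compare_correlation_distributions, compare_module_scores,
                    stratified_correlations)
from .scores import compute_module_scores, normalize_features

#: scaled cross-validation settings used inside multi-seed experiments
FAST_MODEL_CONFIG = ModelConfig(n_train=50, k=5, repeats=1, n_lambda=8)

CLASSIFIER_KINDS = ("ridge", "lasso", "group_lasso", "sparse_group_lasso")


def cohort_features(config: SimConfig):
    """Simulate + featurize + threshold one cohort."""
    tables, metadata, truth = generate_cohort(config)
    fm_raw = featurize_cohort(tables, config.conditions, config.cell_types,
                              config.proteins, config.unstim_condition)
    kept = threshold_features(fm_raw)
    return fm_raw, kept, metadata, truth


def module_recovery(seed: int) -> dict:
    """Default cohort: detect modules and score recovery against truth."""
    config = SimConfig(seed=seed)
    fm_raw, kept, metadata, truth = cohort_features(config)
    corr = correlation_matrix(kept.data)
    clust = cluster_features(corr)
    assignment = extract_modules(clust, bin_adjacency(corr))
    ari = adjusted_rand_score(
        truth.module_of_feature[assignment.module_of.index],
        assignment.module_of)
    out = {
        "seed": seed,
        "n_features_raw": fm_raw.data.shape[1],
        "n_features_kept": kept.data.shape[1],
        "n_modules": len(assignment.module_ids),
        "ari": float(ari),
    }
    if assignment.module_ids:
        per, overall = within_module_correlation(corr, assignment)
        summary = module_summary(assignment, kept.meta)
        out.update({
            "within_module_mean_r": float(per.mean()),
            "overall_mean_r": float(overall),
            "protein_dominant_modules": int(
                (summary["dominant_attribute"] == "protein").sum()),
        })
    return out


def null_sex_calibration(seed: int, n_perm: int = 1000,
                         with_models: bool = True) -> dict:
    """Default cohort has no planted sex effect: count spurious findings.

    Runs SAM (q < 0.01 calls), the per-module correlation Wilcoxon family
    and the module-score KS family (BH rejections at 0.05), and optionally
    the four penalized classifiers (held-out AUC should hover at 0.5).
    """
    config = SimConfig(seed=seed)
    _, kept, metadata, truth = cohort_features(config)
    corr = correlation_matrix(kept.data)
    clust = cluster_features(corr)
    assignment = extract_modules(clust, bin_adjacency(corr))

    sam = sam_permutation_fdr(kept.data, metadata["sex"], n_perm=n_perm,
                              seed=seed)
    strat = stratified_correlations(kept, metadata,
                                    feature_order=clust.leaf_order)
    _, per_module = compare_correlation_distributions(strat, assignment)
    z, _ = normalize_features(kept)
    scores = compute_module_scores(z, assignment)
    ks = compare_module_scores(scores, metadata)

    out = {
        "seed": seed,
        "sam_calls_q01": int((sam.q < 0.01).sum()),
        "wilcoxon_rejections": int(sum(
            t.adjusted_p is not None and t.adjusted_p < 0.05
            for t in per_module)),
        "ks_rejections": int(sum(t.adjusted_p < 0.05 for t in ks)),
    }
    if with_models:
        cfg = PipelineConfig(sim=config, model=FAST_MODEL_CONFIG, seed=seed)
        results = fit_sex_classifiers(kept, assignment, metadata, cfg)
        out["auc"] = {k: float(results[k]["evaluation"]["auc"])
                      for k in CLASSIFIER_KINDS}
    return out


def coordination_recovery(seed: int) -> dict:
    """Planted female-higher coordination in 6 of 8 module programs.

    The stratified per-module Wilcoxon runs on the ground-truth module
    assignment (one module per planted protein program), isolating the
    statistical comparison from module-recovery noise.
    """
    config = sex_coordination_config(seed=seed)
    _, kept, metadata, truth = cohort_features(config)
    truth_assign = ModuleAssignment(
        _truth_modules_as_ids(config, kept.data.columns), 2, 0.5)
    strat = stratified_correlations(kept, metadata)
    glob, per_module = compare_correlation_distributions(strat, truth_assign)

    planted = {"pSTAT1", "pSTAT5", "pSTAT6", "pERK1/2", "pP38", "pCREB"}
    id_to_protein = _module_id_to_protein(config)
    flags = {}
    for t in per_module:
        mid = t.name.removeprefix("module ")
        protein = id_to_protein.get(mid, mid)
        flags[protein] = {
            "adjusted_p": float(t.adjusted_p),
            "female_higher": t.direction == "x_higher",  # groups sorted F, M
        }
    flagged_female = [p for p in planted
                      if p in flags and flags[p]["adjusted_p"] < 0.05
                      and flags[p]["female_higher"]]
    return {
        "seed": seed,
        "global_p": float(glob.p_value),
        "flags": flags,
        "n_planted_flagged_female_higher": len(flagged_female),
        "n_planted": len(planted),
    }


def _truth_modules_as_ids(config: SimConfig, features) -> pd.Series:
    truth = truth_modules(config)[list(features)]
    proteins = sorted({m for m in truth.unique() if m != "unassigned"})
    remap = {p: str(i + 1) for i, p in enumerate(proteins)}
    return truth.map(lambda m: remap.get(m, "unassigned"))


def _module_id_to_protein(config: SimConfig) -> dict[str, str]:
    proteins = sorted({p for p, _, _ in config.response_map})
    return {str(i + 1): p for i, p in enumerate(proteins)}


def shift_recovery(seed: int, with_models: bool = True,
                   model_config: ModelConfig | None = None,
                   n_perm: int = 1000) -> dict:
    """Planted sex-shifted mean responses: SAM grouping and classifiers.

    Checks that SAM's significant lists are non-empty and group purely by
    the planted proteins (male-higher pSTAT1/pTBK1 vs female-higher
    MAPK/CREB arms), and measures held-out classifier AUC.
    """
    config = sex_shift_config(seed=seed)
    _, kept, metadata, truth = cohort_features(config)
    sam = sam_permutation_fdr(kept.data, metadata["sex"], n_perm=n_perm,
                              seed=seed)
    sig = significant_features(sam, fdr=0.01, feature_meta=kept.meta)
    up_prot = set(sig["up"]["protein"]) if len(sig["up"]) else set()
    down_prot = set(sig["down"]["protein"]) if len(sig["down"]) else set()
    out = {
        "seed": seed,
        "n_called": int(len(sig["up"]) + len(sig["down"])),
        "female_higher_proteins": sorted(up_prot),    # d > 0: F minus M
        "male_higher_proteins": sorted(down_prot),
        "protein_pure": (up_prot <= set(SEX_SHIFT_FEMALE_PROTEINS)
                         and down_prot <= set(SEX_SHIFT_MALE_PROTEINS)),
    }
    if with_models:
        corr = correlation_matrix(kept.data)
        assignment = extract_modules(cluster_features(corr),
                                     bin_adjacency(corr))
        cfg = PipelineConfig(sim=config,
                             model=model_config or ModelConfig(),
                             seed=seed)
        results = fit_sex_classifiers(kept, assignment, metadata, cfg)
        out["auc"] = {k: float(results[k]["evaluation"]["auc"])
                      for k in CLASSIFIER_KINDS}
        out["accuracy"] = {k: float(results[k]["evaluation"]["accuracy"])
                           for k in CLASSIFIER_KINDS}
        out["module_score_lasso"] = {
            "auc": float(results["module_score_lasso"]["evaluation"]["auc"]),
            "accuracy": float(
                results["module_score_lasso"]["evaluation"]["accuracy"]),
            "selected": results["module_score_lasso"]["selected_modules"],
        }
    return out
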