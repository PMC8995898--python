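"""End-to-end orchestration: simulate -> features -> modules -> statistics -> models."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from . import features as feat
from . import models as mdl
from . import modules as mod
from . import sam as sam_mod
from . import scores as scr
from . import stats as st
from .config import PipelineConfig
from .simulate import CellEventTable, GroundTruth, generate_cohort

logger = logging.getLogger("cytomodules")


@dataclass
class PipelineResult:
    config: PipelineConfig
    metadata: pd.DataFrame | None = None
    ground_truth: GroundTruth | None = None
    features_raw: feat.FeatureMatrix | None = None
    features: feat.FeatureMatrix | None = None
    correlation: mod.CorrelationMatrix | None = None
    clustering: mod.ClusterResult | None = None
    adjacency: mod.AdjacencyMatrix | None = None
    assignment: mod.ModuleAssignment | None = None
    summary: pd.DataFrame | None = None
    within_module_r: pd.Series | None = None
    overall_r: float | None = None
    zscores: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None
    stratified: st.StratifiedCorrelations | None = None
    stat_tests: dict = field(default_factory=dict)
    sam: sam_mod.SamResult | None = None
    model_results: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig,
                 tables: list[CellEventTable] | None = None,
                 metadata: pd.DataFrame | None = None) -> PipelineResult:
    """Run the full analysis on simulated (default) or supplied event tables.

    Stages: simulate (unless tables are given), derive features, threshold,
    correlate, cluster + extract modules, module scores, sex-stratified
    statistics, SAM differential features, penalized classifiers.  Each
    stage is timed; failures raise with the stage name.
    """
    result = PipelineResult(config=config)
    sim = config.sim

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:               # noqa: BLE001 - annotate stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        result.timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, result.timings[name])
        return out

    if tables is None:
        def _simulate():
            t, m, g = generate_cohort(sim)
            result.ground_truth = g
            return t, m
        tables, metadata = stage("simulate", _simulate)
    if metadata is None:
        raise ValueError("metadata must accompany externally supplied tables")
    result.metadata = metadata

    fz = config.featurizer

    def _derive():
        return feat.featurize_cohort(
            tables, sim.conditions, sim.cell_types, sim.proteins,
            sim.unstim_condition, min_events=fz.min_events,
            cofactor=fz.cofactor)
    result.features_raw = stage("derive", _derive)

    result.features = stage("threshold", lambda: feat.threshold_features(
        result.features_raw, min_mean=fz.min_mean,
        use_absolute=fz.use_absolute))

    mc = config.module
    result.correlation = stage("correlate", lambda: mod.correlation_matrix(
        result.features.data, method=mc.correlation_method))
    result.clustering = stage("cluster", lambda: mod.cluster_features(
        result.correlation, linkage_method=mc.linkage))
    result.adjacency = stage("adjacency", lambda: mod.bin_adjacency(
        result.correlation, cutoff=mc.cutoff))
    result.assignment = stage("modules", lambda: mod.extract_modules(
        result.clustering, result.adjacency,
        min_size=mc.min_size, min_density=mc.min_density))
    if result.assignment.module_ids:
        result.summary = stage("summary", lambda: mod.module_summary(
            result.assignment, result.features.meta))
        result.within_module_r, result.overall_r = stage(
            "within_r", lambda: mod.within_module_correlation(
                result.correlation, result.assignment))

    def _scores():
        z, _ = scr.normalize_features(result.features)
        result.zscores = z
        return scr.compute_module_scores(z, result.assignment)
    result.scores = stage("scores", _scores)

    if config.run_stats:
        sc = config.stats

        def _stratify():
            strat = st.stratified_correlations(
                result.features, result.metadata,
                feature_order=result.clustering.leaf_order)
            glob, per_mod = st.compare_correlation_distributions(
                strat, result.assignment, alpha=sc.alpha)
            ks = st.compare_module_scores(result.scores, result.metadata)
            result.stratified = strat
            return {"correlation_global": glob,
                    "correlation_per_module": per_mod,
                    "module_score_ks": ks}
        result.stat_tests = stage("stratify", _stratify)

        result.sam = stage("sam", lambda: sam_mod.sam_permutation_fdr(
            result.features.data, result.metadata["sex"],
            n_perm=sc.n_perm, seed=config.seed))

    if config.model.enabled:
        result.model_results = stage("models", lambda: fit_sex_classifiers(
            result.features, result.assignment, result.metadata,
            config))
    return result


def fit_sex_classifiers(fm: feat.FeatureMatrix,
                        assignment: mod.ModuleAssignment,
                        metadata: pd.DataFrame,
                        config: PipelineConfig) -> dict:
    """Train/test the four penalty modes plus the module-score lasso.

    Donors are split once (default 50 train / rest test); standardization
    and module-score normalization use training donors only.
    """
    mcfg = config.model
    train, test = mdl.split_train_test(metadata, n_train=mcfg.n_train,
                                       seed=config.seed)
    y = mdl.encode_labels(metadata)
    Xtr_raw, Xte_raw = fm.data.loc[train], fm.data.loc[test]
    # complete-case features only (solver needs dense input)
    cols = [c for c in fm.data.columns
            if Xtr_raw[c].notna().all() and Xte_raw[c].notna().all()]
    Xtr, params = mdl.standardize(Xtr_raw[cols])
    Xte, _ = mdl.standardize(Xte_raw[cols], params)
    groups = {f: g for f, g in
              mdl.groups_from_assignment(assignment.module_of).items()
              if f in cols}

    family = {
        "ridge": mdl.PenaltySpec.ridge(1.0),
        "lasso": mdl.PenaltySpec.lasso(1.0),
        "group_lasso": mdl.PenaltySpec.group_lasso(1.0, groups),
        "sparse_group_lasso": mdl.PenaltySpec.sparse_group(
            1.0, mcfg.sgl_alpha, groups),
    }
    out = {}
    for name, template in family.items():
        cv = mdl.cross_validate_lambda(
            Xtr, y[train], [template], k=min(mcfg.k, len(train)),
            repeats=mcfg.repeats, n_lambda=mcfg.n_lambda, seed=config.seed)
        fit = mdl.fit_penalized_logistic(Xtr, y[train], cv.best_spec)
        fit.train_donors = list(train)
        out[name] = {"fit": fit, "cv": cv,
                     "evaluation": mdl.evaluate_model(fit, Xte, y[test])}

    score_tr = scr.module_scores_from_features(fm, assignment,
                                               train_donors=train)
    out["module_score_lasso"] = mdl.fit_module_score_model(
        score_tr, metadata, seed=config.seed, n_train=mcfg.n_train,
        k=mcfg.k, repeats=mcfg.repeats, n_lambda=mcfg.n_lambda)
    return out
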