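"""Penalized logistic solver: prox operators, fits, CV, evaluation.

statsmodels' Newton-solved Logit is the independent oracle for the
unpenalized case.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cytomodules import (PenaltySpec, auc_score, cross_validate_lambda,
                         evaluate_model, fit_module_score_model,
                         fit_penalized_logistic, prox_sparse_group, roc_curve,
                         split_train_test, standardize)
from cytomodules.models import encode_labels, lambda_grid, lambda_max


def _problem(n=40, p=5, seed=0, beta=None, as_frame=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = rng.normal(size=p)
    eta = X @ beta
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
    Xf = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    Xs, _ = standardize(Xf)
    return (Xs if as_frame else Xs.to_numpy()), y


class TestProx:
    def test_zero_thresholds_are_identity(self):
        v = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(prox_sparse_group(v, 0.0, 0.0), v)

    def test_group_annihilation(self):
        v = np.array([0.3, -0.2, 0.1])
        out = prox_sparse_group(v, 0.05, 10.0)
        np.testing.assert_allclose(out, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_kkt_residual_on_random_blocks(self, seed):
        """Output satisfies the prox subproblem's optimality condition:
        0 in u - v + l1*sign(u) + l2*u/||u|| (min-norm subgradient)."""
        rng = np.random.default_rng(seed)
        v = rng.normal(size=5)
        l1, l2 = rng.uniform(0.01, 0.5, size=2)
        u = prox_sparse_group(v, l1, l2)
        if np.linalg.norm(u) == 0:
            # zero is optimal iff ||soft(v, l1)||_2 <= l2
            assert np.linalg.norm(np.sign(v) * np.maximum(np.abs(v) - l1, 0)
                                  ) <= l2 + 1e-12
        else:
            grad = u - v + l2 * u / np.linalg.norm(u)
            resid = np.where(u != 0, grad + l1 * np.sign(u),
                             np.maximum(np.abs(grad) - l1, 0.0))
            assert np.max(np.abs(resid)) < 1e-8


class TestFit:
    def test_huge_lambda_zeroes_coefficients(self):
        X, y = _problem(seed=1)
        fit = fit_penalized_logistic(X, y, PenaltySpec.lasso(100.0))
        assert (fit.coef == 0.0).all()
        prev = y.mean()
        assert fit.intercept == pytest.approx(np.log(prev / (1 - prev)),
                                              abs=1e-4)

    @pytest.mark.parametrize("kind", ["ridge", "lasso", "group_lasso",
                                      "sparse_group"])
    def test_unpenalized_matches_newton_oracle(self, kind):
        X, y = _problem(n=40, p=5, seed=2)
        groups = {f: str(i % 2) for i, f in enumerate(X.columns)}
        spec = {"ridge": PenaltySpec.ridge(0.0),
                "lasso": PenaltySpec.lasso(0.0),
                "group_lasso": PenaltySpec.group_lasso(0.0, groups),
                "sparse_group": PenaltySpec.sparse_group(0.0, 0.5, groups),
                }[kind]
        fit = fit_penalized_logistic(X, y, spec, tol=1e-14, max_iter=50000)
        ref = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
        assert np.max(np.abs(fit.coef.to_numpy() - ref.params[1:])) < 1e-4
        assert abs(fit.intercept - ref.params[0]) < 1e-4

    def test_objective_monotone_under_backtracking(self):
        X, y = _problem(n=60, p=10, seed=3)
        groups = {f: str(i % 3) for i, f in enumerate(X.columns)}
        fit = fit_penalized_logistic(
            X, y, PenaltySpec.sparse_group(0.05, 0.5, groups))
        diffs = np.diff(fit.objective_path)
        assert (diffs <= 1e-12).all()

    @pytest.mark.parametrize("spec_fn", [
        lambda g: PenaltySpec.ridge(0.1),
        lambda g: PenaltySpec.lasso(0.05),
        lambda g: PenaltySpec.group_lasso(0.05, g),
        lambda g: PenaltySpec.sparse_group(0.05, 0.5, g),
    ])
    def test_kkt_residual_at_convergence(self, spec_fn):
        X, y = _problem(n=60, p=12, seed=4)
        groups = {f: str(i % 4) for i, f in enumerate(X.columns)}
        fit = fit_penalized_logistic(X, y, spec_fn(groups), tol=1e-12,
                                     max_iter=50000)
        assert fit.kkt_residual <= 1e-4

    def test_group_lasso_respects_groups(self):
        """Only one informative group: zero patterns follow group lines."""
        rng = np.random.default_rng(5)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 9)),
                         columns=[f"x{j}" for j in range(9)])
        eta = X[["x3", "x4", "x5"]].to_numpy() @ np.array([1.5, -1.2, 1.0])
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        Xs, _ = standardize(X)
        groups = {f"x{j}": str(j // 3) for j in range(9)}
        fit = fit_penalized_logistic(
            Xs, y, PenaltySpec.group_lasso(0.08, groups))
        by_group = {g: [f"x{j}" for j in range(9) if groups[f"x{j}"] == g]
                    for g in "012"}
        nonzero = {g: (fit.coef[fs] != 0).any() for g, fs in by_group.items()}
        assert nonzero["1"]                        # informative group kept
        for g in ("0", "2"):
            members_zeroed = (fit.coef[by_group[g]] == 0).all()
            assert members_zeroed == (not nonzero[g])

    def test_lasso_equals_singleton_sgl(self):
        X, y = _problem(n=50, p=8, seed=6)
        singles = {f: f for f in X.columns}
        lam = 0.05
        f1 = fit_penalized_logistic(X, y, PenaltySpec.lasso(lam), tol=1e-13,
                                    max_iter=50000)
        f2 = fit_penalized_logistic(
            X, y, PenaltySpec.sparse_group(lam, 1.0, singles), tol=1e-13,
            max_iter=50000)
        assert np.max(np.abs(f1.coef - f2.coef)) < 1e-6

    def test_missing_values_rejected(self):
        X, y = _problem(seed=7)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_penalized_logistic(X, y, PenaltySpec.lasso(0.1))

    def test_lambda_max_zeroes_solution(self):
        X, y = _problem(n=60, p=10, seed=8)
        groups = {f: str(i % 3) for i, f in enumerate(X.columns)}
        for spec in (PenaltySpec.lasso(1.0),
                     PenaltySpec.group_lasso(1.0, groups),
                     PenaltySpec.sparse_group(1.0, 0.5, groups)):
            lmax = lambda_max(X, y, spec)
            fit = fit_penalized_logistic(X, y,
                                         spec.with_lambda(lmax * 1.001))
            assert (fit.coef == 0.0).all()
            fit2 = fit_penalized_logistic(X, y,
                                          spec.with_lambda(lmax * 0.8))
            assert (fit2.coef != 0.0).any()

    def test_lasso_support_nests_along_path(self):
        """Warm-started descending-lambda path: support only grows (checked
        on a small well-conditioned instance)."""
        X, y = _problem(n=80, p=6, seed=9)
        grid = lambda_grid(X, y, PenaltySpec.lasso(1.0), n_lambda=12,
                           decades=2.0)
        prev_support: set = set()
        warm = None
        for lam in grid:
            fit = fit_penalized_logistic(X, y, PenaltySpec.lasso(float(lam)),
                                         init=warm, tol=1e-12)
            warm = (fit.intercept, fit.coef.to_numpy())
            support = set(fit.selected)
            assert prev_support <= support
            prev_support = support


class TestCrossValidation:
    def test_single_point_grid(self):
        X, y = _problem(n=30, p=4, seed=10)
        cv = cross_validate_lambda(X, y, [PenaltySpec.lasso(1.0)], k=3,
                                   repeats=1, n_lambda=1, seed=0)
        assert cv.table.shape[0] == 1
        assert cv.best_spec.kind == "lasso"

    def test_seeded_fold_determinism(self):
        X, y = _problem(n=40, p=6, seed=11)
        kw = dict(k=4, repeats=1, n_lambda=5, seed=3)
        cv1 = cross_validate_lambda(X, y, [PenaltySpec.lasso(1.0)], **kw)
        cv2 = cross_validate_lambda(X, y, [PenaltySpec.lasso(1.0)], **kw)
        assert cv1.best_spec.lam == cv2.best_spec.lam
        pd.testing.assert_frame_equal(cv1.table, cv2.table)

    def test_dense_weak_signal_prefers_ridge(self):
        """Many small effects: elastic-net CV picks alpha = 0 (ridge-like)
        most of the time, mirroring dense-signal behavior."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(300 + seed)
            n, p = 100, 60
            beta = 0.18 * rng.choice([-1.0, 1.0], size=p)   # dense, weak
            X = pd.DataFrame(rng.normal(size=(n, p)),
                             columns=[f"x{j}" for j in range(p)])
            eta = X.to_numpy() @ beta
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
            Xs, _ = standardize(X)
            family = [PenaltySpec.elastic_net(1.0, a) for a in (0.0, 0.5, 1.0)]
            cv = cross_validate_lambda(Xs, y, family, k=5, repeats=2,
                                       n_lambda=10, seed=seed, tol=1e-7,
                                       max_iter=2000)
            wins += cv.best_spec.alpha == 0.0
        assert wins >= 0.75 * n_seeds


class TestEvaluation:
    def test_perfect_and_reversed_scores(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert auc_score(s, y) == 1.0
        assert auc_score(-s, y) == 0.0
        fpr, tpr = roc_curve(s, y)
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_tie_handling_gives_half(self):
        assert auc_score([0.5] * 10, [0, 1] * 5) == 0.5

    def test_null_scores_center_on_half(self):
        aucs = []
        rng = np.random.default_rng(12)
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            if len(np.unique(y)) < 2:
                continue
            aucs.append(auc_score(rng.normal(size=50), y))
        mean, se = np.mean(aucs), np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(mean - 0.5) < 1.96 * se + 0.02

    def test_single_class_test_set(self):
        X, y = _problem(n=30, p=3, seed=13)
        fit = fit_penalized_logistic(X, y, PenaltySpec.ridge(0.1))
        with pytest.warns(UserWarning, match="single-class"):
            out = evaluate_model(fit, X, np.ones(len(X), dtype=int))
        assert np.isnan(out["auc"])


class TestSplits:
    def test_fifty_thirtysix(self):
        metadata = pd.DataFrame({"sex": ["F", "M"] * 43},
                                index=[f"D{i}" for i in range(86)])
        train, test = split_train_test(metadata, n_train=50, seed=0)
        assert len(train) == 50 and len(test) == 36
        assert set(train) | set(test) == set(metadata.index)
        assert set(train) & set(test) == set()
        again, _ = split_train_test(metadata, n_train=50, seed=0)
        assert train == again

    def test_train_must_be_smaller_than_cohort(self):
        metadata = pd.DataFrame({"sex": ["F", "M"]}, index=["a", "b"])
        with pytest.raises(ValueError):
            split_train_test(metadata, n_train=2)


class TestModuleScoreModel:
    def _scores(self, seed, n=86, shift_cols=("1", "5"), shift=1.2):
        rng = np.random.default_rng(seed)
        cols = [str(i) for i in range(1, 9)]
        scores = pd.DataFrame(rng.normal(size=(n, 8)), columns=cols,
                              index=[f"D{i}" for i in range(n)])
        sexes = np.array(["F", "M"] * (n // 2))
        rng.shuffle(sexes)
        for c in shift_cols:
            scores.loc[sexes == "M", c] += shift
        metadata = pd.DataFrame({"sex": sexes}, index=scores.index)
        return scores, metadata

    def test_planted_modules_selected(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            scores, metadata = self._scores(400 + seed)
            out = fit_module_score_model(scores, metadata, seed=seed,
                                         k=5, repeats=1, n_lambda=10)
            selected = set(out["selected_modules"])
            hits += {"1", "5"} <= selected
        assert hits >= 0.75 * n_seeds

    def test_single_module_reduces_to_univariate(self):
        scores, metadata = self._scores(99, shift_cols=("1",))
        out = fit_module_score_model(scores[["1"]], metadata, seed=0,
                                     k=5, repeats=1, n_lambda=8)
        assert list(out["fit"].coef.index) == ["1"]
        assert out["evaluation"]["auc"] > 0.6
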