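"""Penalized logistic classifiers of donor sex with module-group structure.

Four penalty modes over one proximal-gradient solver:

  ridge               lam * ||b||_2^2 / 2                     (smooth)
  lasso               lam * ||b||_1
  elastic net         lam * [a ||b||_1 + (1-a) ||b||_2^2 / 2]
  group lasso         lam * sum_g sqrt(p_g) ||b_g||_2
  sparse group lasso  lam * [a ||b||_1 + (1-a) sum_g sqrt(p_g) ||b_g||_2]

The smooth part is the mean logistic deviance; the intercept is never
penalized.  Backtracking guarantees a monotone objective; a Nesterov
acceleration step is taken only when it does not break monotonicity.
Group weights sqrt(p_g) follow the standard group-lasso formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


# -- penalty specification ---------------------------------------------------

@dataclass
class PenaltySpec:
    kind: str                 # ridge | lasso | group_lasso | sparse_group
    lam: float
    alpha: float = 1.0        # l1 mixing fraction (sparse_group only)
    groups: Mapping[str, str] | None = None   # feature -> group id

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.kind not in ("ridge", "lasso", "elastic_net", "group_lasso",
                             "sparse_group"):
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if self.kind in ("group_lasso", "sparse_group") and self.groups is None:
            raise ValueError(f"{self.kind} requires a feature->group mapping")

    @classmethod
    def ridge(cls, lam: float) -> "PenaltySpec":
        return cls("ridge", lam, alpha=0.0)

    @classmethod
    def lasso(cls, lam: float) -> "PenaltySpec":
        return cls("lasso", lam, alpha=1.0)

    @classmethod
    def elastic_net(cls, lam: float, alpha: float) -> "PenaltySpec":
        return cls("elastic_net", lam, alpha=alpha)

    @classmethod
    def group_lasso(cls, lam: float, groups: Mapping[str, str]) -> "PenaltySpec":
        return cls("group_lasso", lam, alpha=0.0, groups=groups)

    @classmethod
    def sparse_group(cls, lam: float, alpha: float,
                     groups: Mapping[str, str]) -> "PenaltySpec":
        return cls("sparse_group", lam, alpha=alpha, groups=groups)

    def with_lambda(self, lam: float) -> "PenaltySpec":
        return PenaltySpec(self.kind, lam, self.alpha, self.groups)


def groups_from_assignment(module_of: pd.Series,
                           singleton_unassigned: bool = True
                           ) -> dict[str, str]:
    """Feature -> group map from a module assignment.

    Unassigned features become singleton groups by default (each its own
    group), or one shared 'unassigned' group when requested.
    """
    out = {}
    for f, m in module_of.items():
        if m == "unassigned" and singleton_unassigned:
            out[f] = f"singleton:{f}"
        else:
            out[f] = str(m)
    return out


def _group_blocks(features: Sequence[str],
                  groups: Mapping[str, str] | None
                  ) -> list[tuple[np.ndarray, float]]:
    """(index array, sqrt(p_g) weight) per group, singletons if no mapping."""
    if groups is None:
        return [(np.array([j]), 1.0) for j in range(len(features))]
    by_group: dict[str, list[int]] = {}
    for j, f in enumerate(features):
        by_group.setdefault(str(groups[f]), []).append(j)
    return [(np.asarray(idx), float(np.sqrt(len(idx))))
            for idx in by_group.values()]


# -- proximal machinery ------------------------------------------------------

def soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def prox_sparse_group(v: np.ndarray, l1: float, l2: float) -> np.ndarray:
    """Prox of b -> l1*||b||_1 + l2*||b||_2 for one coefficient block.

    Elementwise soft-threshold by l1, then group soft-threshold: scale by
    max(0, 1 - l2 / ||.||_2); l2 already includes the sqrt(p_g) weight.
    """
    u = soft_threshold(np.asarray(v, dtype=float), l1)
    if l2 > 0:
        norm = np.linalg.norm(u)
        u = np.zeros_like(u) if norm <= l2 else (1.0 - l2 / norm) * u
    return u


def _penalty_value(beta: np.ndarray, spec: PenaltySpec,
                   blocks: list[tuple[np.ndarray, float]]) -> float:
    lam, a = spec.lam, spec.alpha
    if spec.kind == "ridge":
        return 0.5 * lam * float(beta @ beta)
    if spec.kind == "lasso":
        return lam * float(np.abs(beta).sum())
    if spec.kind == "elastic_net":
        return lam * (spec.alpha * float(np.abs(beta).sum())
                      + 0.5 * (1 - spec.alpha) * float(beta @ beta))
    group_term = sum(w * np.linalg.norm(beta[idx]) for idx, w in blocks)
    if spec.kind == "group_lasso":
        return lam * float(group_term)
    return lam * (a * float(np.abs(beta).sum()) + (1 - a) * float(group_term))


def _prox(beta: np.ndarray, t: float, spec: PenaltySpec,
          blocks: list[tuple[np.ndarray, float]]) -> np.ndarray:
    lam, a = spec.lam, spec.alpha
    if spec.kind == "ridge" or lam == 0.0:
        return beta.copy()
    if spec.kind == "lasso":
        return soft_threshold(beta, t * lam)
    if spec.kind == "elastic_net":
        return soft_threshold(beta, t * lam * spec.alpha)
    out = np.empty_like(beta)
    l1 = t * lam * (a if spec.kind == "sparse_group" else 0.0)
    gfrac = (1 - a) if spec.kind == "sparse_group" else 1.0
    for idx, w in blocks:
        out[idx] = prox_sparse_group(beta[idx], l1, t * lam * gfrac * w)
    return out


def _logistic_loss_grad(X: np.ndarray, y: np.ndarray, b0: float,
                        beta: np.ndarray
                        ) -> tuple[float, float, np.ndarray]:
    """Mean logistic deviance loss and gradients (intercept, coefficients)."""
    eta = b0 + X @ beta
    # log(1 + exp(-s*eta)) computed stably
    s = 2.0 * y - 1.0
    z = -s * eta
    loss = float(np.mean(np.logaddexp(0.0, z)))
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    r = (p - y) / len(y)
    return loss, float(r.sum()), X.T @ r


@dataclass
class ModelFit:
    intercept: float
    coef: pd.Series
    spec: PenaltySpec
    converged: bool
    n_iter: int
    objective: float
    objective_path: np.ndarray
    kkt_residual: float
    train_donors: list[str] = field(default_factory=list)
    standardization: pd.DataFrame | None = None

    @property
    def selected(self) -> list[str]:
        return list(self.coef.index[self.coef != 0.0])

    def decision_function(self, X: pd.DataFrame) -> pd.Series:
        Xs = X[self.coef.index]
        if self.standardization is not None:
            Xs = (Xs - self.standardization["mean"]) / self.standardization["sd"]
        return self.intercept + Xs @ self.coef

    def predict_proba(self, X: pd.DataFrame) -> pd.Series:
        eta = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(-eta))


def standardize(X: pd.DataFrame, params: pd.DataFrame | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-standardize (train-derived params reusable on test data)."""
    if params is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = sd.replace(0.0, 1.0)
        params = pd.DataFrame({"mean": mean, "sd": sd})
    return (X - params["mean"]) / params["sd"], params


def fit_penalized_logistic(X: pd.DataFrame, y: Sequence[int],
                           spec: PenaltySpec, tol: float = 1e-10,
                           max_iter: int = 20000,
                           init: tuple[float, np.ndarray] | None = None
                           ) -> ModelFit:
    """Minimize mean logistic loss + penalty by monotone proximal gradient.

    ``X`` should be column-standardized (training statistics); ``y`` is
    binary 0/1.  The intercept is unpenalized.  Convergence is declared
    when the objective decrease falls below ``tol * (1 + |objective|)``;
    hitting ``max_iter`` flags the fit as non-converged rather than failing
    silently.
    """
    features = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("X contains missing/non-finite values; "
                         "impute or drop incomplete features first")
    yv = np.asarray(y, dtype=float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    blocks = _group_blocks(features, spec.groups)

    if init is not None:
        b0, beta = float(init[0]), np.array(init[1], dtype=float)
    else:
        b0, beta = 0.0, np.zeros(Xv.shape[1])
    ridge_lam = (spec.lam if spec.kind == "ridge"
                 else spec.lam * (1 - spec.alpha)
                 if spec.kind == "elastic_net" else 0.0)

    def smooth(b0_, beta_):
        loss, g0, g = _logistic_loss_grad(Xv, yv, b0_, beta_)
        if ridge_lam:
            loss += 0.5 * ridge_lam * float(beta_ @ beta_)
            g = g + ridge_lam * beta_
        return loss, g0, g

    def objective(b0_, beta_):
        loss, _, _ = smooth(b0_, beta_)     # includes any smooth l2^2 part
        if spec.kind == "ridge":
            return loss
        if spec.kind == "elastic_net":
            return loss + spec.lam * spec.alpha * float(np.abs(beta_).sum())
        return loss + _penalty_value(beta_, spec, blocks)

    t = 1.0
    obj = objective(b0, beta)
    path = [obj]
    mom_b0, mom_beta = b0, beta            # Nesterov lookahead point
    theta = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        loss_m, g0, g = smooth(mom_b0, mom_beta)
        # backtracking from the momentum point
        while True:
            cand_b0 = mom_b0 - t * g0
            cand = _prox(mom_beta - t * g, t, spec, blocks)
            db0, db = cand_b0 - mom_b0, cand - mom_beta
            quad = loss_m + g0 * db0 + g @ db + \
                (db0 * db0 + db @ db) / (2.0 * t)
            loss_c, _, _ = smooth(cand_b0, cand)
            if loss_c <= quad + 1e-12:
                break
            t *= 0.5
            if t < 1e-14:
                break
        new_obj = objective(cand_b0, cand)
        if new_obj <= obj:
            # accelerated step accepted; update momentum
            theta_new = (1.0 + np.sqrt(1.0 + 4.0 * theta * theta)) / 2.0
            mom_b0 = cand_b0 + (theta - 1.0) / theta_new * (cand_b0 - b0)
            mom_beta = cand + (theta - 1.0) / theta_new * (cand - beta)
            theta = theta_new
            b0, beta = cand_b0, cand
        else:
            # fall back to a plain proximal step from the current iterate
            loss_i, g0, g = smooth(b0, beta)
            while True:
                cand_b0 = b0 - t * g0
                cand = _prox(beta - t * g, t, spec, blocks)
                db0, db = cand_b0 - b0, cand - beta
                quad = loss_i + g0 * db0 + g @ db + \
                    (db0 * db0 + db @ db) / (2.0 * t)
                loss_c, _, _ = smooth(cand_b0, cand)
                if loss_c <= quad + 1e-12:
                    break
                t *= 0.5
                if t < 1e-14:
                    break
            new_obj = objective(cand_b0, cand)
            if new_obj > obj:        # no further progress possible
                converged = True
                path.append(obj)
                break
            b0, beta = cand_b0, cand
            mom_b0, mom_beta, theta = b0, beta, 1.0
        path.append(new_obj)
        if obj - new_obj < tol * (1.0 + abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
        t = min(t * 2.0, 1e4)        # gentle step-size recovery

    if not converged:
        warnings.warn(f"{spec.kind} fit did not converge in {max_iter} "
                      "iterations")
    _, g0, g = smooth(b0, beta)
    t_kkt = 1.0
    res = np.max(np.abs(beta - _prox(beta - t_kkt * g, t_kkt, spec, blocks))) \
        / t_kkt
    kkt = float(max(res, abs(g0)))
    return ModelFit(intercept=float(b0),
                    coef=pd.Series(beta, index=features, name="coef"),
                    spec=spec, converged=converged, n_iter=it,
                    objective=float(objective(b0, beta)),
                    objective_path=np.asarray(path),
                    kkt_residual=kkt)


# -- lambda grids and cross-validation ---------------------------------------

def lambda_max(X: pd.DataFrame, y: Sequence[int], spec: PenaltySpec) -> float:
    """Smallest lambda at which the all-zero coefficient vector is optimal.

    For ridge (never sparse) this returns a gradient-scale heuristic used
    only to anchor the grid.
    """
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    p0 = yv.mean()
    b0 = float(np.log(p0 / (1 - p0))) if 0 < p0 < 1 else 0.0
    _, _, g = _logistic_loss_grad(Xv, yv, b0, np.zeros(Xv.shape[1]))
    blocks = _group_blocks(list(X.columns), spec.groups)
    if spec.kind == "lasso":
        return float(np.max(np.abs(g)))
    if spec.kind == "ridge" or (spec.kind == "elastic_net" and spec.alpha == 0):
        # no sparsity threshold exists; anchor the grid well above the
        # gradient scale so CV can reach heavily-shrunk solutions
        return 100.0 * float(np.max(np.abs(g)))
    if spec.kind == "elastic_net":
        return float(np.max(np.abs(g))) / spec.alpha
    if spec.kind == "group_lasso":
        return float(max(np.linalg.norm(g[idx]) / w for idx, w in blocks))
    a = spec.alpha
    if a == 1.0:
        return float(np.max(np.abs(g)))

    def zero_ok(lam: float) -> bool:
        return all(np.linalg.norm(soft_threshold(g[idx], lam * a))
                   <= lam * (1 - a) * w + 1e-15 for idx, w in blocks)

    hi = float(np.max(np.abs(g))) / min(a if a > 0 else 1.0, 1 - a) + 1e-12
    lo = 0.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if zero_ok(mid):
            hi = mid
        else:
            lo = mid
    return hi


def lambda_grid(X: pd.DataFrame, y: Sequence[int], spec: PenaltySpec,
                n_lambda: int = 50, decades: float = 4.0) -> np.ndarray:
    lmax = lambda_max(X, y, spec)
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_lambda)


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Class-stratified fold assignment; every fold sees both classes."""
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    for f in range(k):
        held = y[fold == f]
        if len(np.unique(held)) < 2:
            warnings.warn("fold lacked a class; refolding")
            return _stratified_folds(y, k, rng)
    return [np.flatnonzero(fold == f) for f in range(k)]


@dataclass
class CVResult:
    best_spec: PenaltySpec
    table: pd.DataFrame       # kind, alpha, lambda, mean_deviance


def cross_validate_lambda(X: pd.DataFrame, y: Sequence[int],
                          spec_family: Sequence[PenaltySpec],
                          k: int = 10, repeats: int = 3,
                          n_lambda: int = 20, seed: int = 0,
                          tol: float = 1e-8, max_iter: int = 5000
                          ) -> CVResult:
    """Repeated k-fold CV over a penalty family and its lambda paths.

    Each template spec's lambda is swept over a log grid from its own
    lambda_max down; the winner minimizes mean held-out deviance, ties
    resolved toward the larger lambda (stronger regularization).
    """
    yv = np.asarray(y, dtype=float)
    if k > len(yv):
        raise ValueError("k exceeds the number of training donors")
    rows = []
    candidates: list[tuple[PenaltySpec, float]] = []
    for template in spec_family:
        grid = lambda_grid(X, yv, template, n_lambda=n_lambda)
        deviances = np.zeros(len(grid))
        count = 0
        for rep in range(repeats):
            rng = np.random.default_rng(seed + 7919 * rep)
            folds = _stratified_folds(yv, k, rng)
            for held in folds:
                train = np.setdiff1d(np.arange(len(yv)), held)
                Xtr, params = standardize(X.iloc[train])
                Xte, _ = standardize(X.iloc[held], params)
                warm = None
                with warnings.catch_warnings():
                    warnings.filterwarnings(
                        "ignore", message=".*did not converge.*")
                    for gi, lam in enumerate(grid):  # warm start down the path
                        fit = fit_penalized_logistic(
                            Xtr, yv[train], template.with_lambda(float(lam)),
                            tol=tol, max_iter=max_iter, init=warm)
                        warm = (fit.intercept, fit.coef.to_numpy())
                        eta = (fit.intercept
                               + Xte.to_numpy() @ fit.coef.to_numpy())
                        s = 2.0 * yv[held] - 1.0
                        deviances[gi] += 2.0 * float(
                            np.mean(np.logaddexp(0.0, -s * eta)))
                count += 1
        deviances /= count
        for lam, dev in zip(grid, deviances):
            rows.append({"kind": template.kind, "alpha": template.alpha,
                         "lambda": float(lam), "mean_deviance": float(dev)})
            candidates.append((template.with_lambda(float(lam)), float(dev)))
    table = pd.DataFrame(rows)
    best_dev = min(d for _, d in candidates)
    best = max((s for s, d in candidates if d <= best_dev + 1e-12),
               key=lambda s: s.lam)
    return CVResult(best, table)


# -- evaluation --------------------------------------------------------------

def auc_score(scores: Sequence[float], y: Sequence[int]) -> float:
    """Rank-based AUC (Mann-Whitney with midranks; ties count half)."""
    scores = np.asarray(scores, dtype=float)
    yv = np.asarray(y, dtype=int)
    n1 = int(yv.sum())
    n0 = len(yv) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    from scipy.stats import rankdata
    r = rankdata(scores)
    return float((r[yv == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve(scores: Sequence[float], y: Sequence[int]
              ) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) swept over all score thresholds, ends pinned at 0 and 1."""
    scores = np.asarray(scores, dtype=float)
    yv = np.asarray(y, dtype=int)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(yv[order])
    fps = np.cumsum(1 - yv[order])
    # collapse threshold ties
    distinct = np.append(np.flatnonzero(np.diff(scores[order])), len(scores) - 1)
    tpr = np.concatenate([[0.0], tps[distinct] / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps[distinct] / max(fps[-1], 1)])
    return fpr, tpr


def evaluate_model(fit: ModelFit, X_test: pd.DataFrame,
                   y_test: Sequence[int]) -> dict:
    """Held-out accuracy at p=0.5, ROC curve and rank AUC."""
    proba = fit.predict_proba(X_test).to_numpy()
    yv = np.asarray(y_test, dtype=int)
    acc = float(np.mean((proba >= 0.5).astype(int) == yv))
    if len(np.unique(yv)) < 2:
        warnings.warn("single-class test set: AUC undefined")
        return {"accuracy": acc, "auc": float("nan"), "roc": None,
                "n_test": len(yv)}
    fpr, tpr = roc_curve(proba, yv)
    return {"accuracy": acc, "auc": auc_score(proba, yv),
            "roc": (fpr, tpr), "n_test": len(yv)}


# -- cohort-level conveniences ------------------------------------------------

def split_train_test(metadata: pd.DataFrame, n_train: int = 50, seed: int = 0,
                     stratify: bool = False, group_col: str = "sex"
                     ) -> tuple[list[str], list[str]]:
    """Random disjoint, exhaustive train/test donor split (default 50/36)."""
    donors = np.asarray(metadata.index)
    if n_train >= len(donors):
        raise ValueError("n_train must be smaller than the cohort")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list[int] = []
        for cls in np.unique(metadata[group_col]):
            idx = np.flatnonzero((metadata[group_col] == cls).to_numpy())
            n_cls = int(round(n_train * len(idx) / len(donors)))
            rng.shuffle(idx)
            train_idx.extend(idx[:n_cls])
        train = set(np.asarray(train_idx)[:n_train])
    else:
        classes = metadata[group_col].to_numpy()
        for _ in range(1000):
            perm = rng.permutation(len(donors))
            train = set(perm[:n_train])
            if len(np.unique(classes[list(train)])) == 2:
                break
            warnings.warn("training split lacked a class; resampling")
    train_ids = [d for i, d in enumerate(donors) if i in train]
    test_ids = [d for i, d in enumerate(donors) if i not in train]
    return train_ids, test_ids


def encode_labels(metadata: pd.DataFrame, group_col: str = "sex",
                  positive: str = "F") -> pd.Series:
    return (metadata[group_col] == positive).astype(int)


def fit_module_score_model(scores: pd.DataFrame, metadata: pd.DataFrame,
                           seed: int = 0, n_train: int = 50,
                           k: int = 10, repeats: int = 3,
                           n_lambda: int = 20) -> dict:
    """Lasso logistic on personalized module scores; returns fit + evaluation."""
    train, test = split_train_test(metadata, n_train=n_train, seed=seed)
    y = encode_labels(metadata)
    Xtr_raw, Xte_raw = scores.loc[train], scores.loc[test]
    if Xtr_raw.isna().any().any() or Xte_raw.isna().any().any():
        # donors missing every member of a module: impute with train mean
        fill = Xtr_raw.mean(axis=0)
        Xtr_raw = Xtr_raw.fillna(fill)
        Xte_raw = Xte_raw.fillna(fill)
    Xtr, params = standardize(Xtr_raw)
    cv = cross_validate_lambda(Xtr, y[train], [PenaltySpec.lasso(1.0)],
                               k=min(k, len(train)), repeats=repeats,
                               n_lambda=n_lambda, seed=seed)
    fit = fit_penalized_logistic(Xtr, y[train], cv.best_spec)
    fit.train_donors = list(train)
    fit.standardization = params
    ev = evaluate_model(fit, Xte_raw, y[test])
    return {"fit": fit, "cv": cv, "evaluation": ev,
            "selected_modules": fit.selected,
            "train": list(train), "test": list(test)}
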