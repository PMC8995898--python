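"""Sex-stratified correlation structure and distributional comparisons.

The statistical primitives (Wilcoxon rank-sum, two-sample Kolmogorov-
Smirnov, Benjamini-Hochberg) are implemented here rather than delegated:
they are part of the analysis surface and are cross-checked against
independent implementations in the test suite.

Caveat replicated deliberately: the correlation-distribution comparisons
treat pairwise correlation coefficients as exchangeable observations even
though pairs sharing a feature are dependent; a donor-bootstrap alternative
is provided for a dependence-honest global comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from scipy.stats import norm, rankdata

from .modules import UNASSIGNED, CorrelationMatrix, ModuleAssignment, correlation_matrix

WILCOXON_EXACT_MAX = 10


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    n_x: int = 0
    n_y: int = 0
    summary_x: float = float("nan")
    summary_y: float = float("nan")
    direction: str | None = None
    note: str | None = None


@dataclass
class StratifiedCorrelations:
    """Per-group correlation matrices over one shared feature order."""

    groups: dict[str, CorrelationMatrix]
    feature_order: list[str]

    @property
    def group_labels(self) -> list[str]:
        return list(self.groups)


# -- primitives --------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment: p * m / rank, then enforce monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _rank_sum_exact_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p for the rank sum over all C(n, n1) splits."""
    lo = hi = 0
    total = 0
    for idx in combinations(range(len(ranks)), n1):
        w = ranks[list(idx)].sum()
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(lo / total, hi / total))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      name: str = "wilcoxon") -> TestResult:
    """Two-sided Wilcoxon rank-sum test with midranks.

    Exact enumeration over all rank splits when both samples have <= 10
    observations; otherwise a normal approximation with tie-corrected
    variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    w = float(ranks[:n1].sum())
    result = TestResult(name, w, 1.0, n_x=n1, n_y=n2,
                        summary_x=float(np.median(x)),
                        summary_y=float(np.median(y)))
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1")
        result.note = "degenerate: all values tied"
        return result
    if n1 <= WILCOXON_EXACT_MAX and n2 <= WILCOXON_EXACT_MAX:
        result.p_value = _rank_sum_exact_p(ranks, n1, w)
        result.note = "exact"
    else:
        n = n1 + n2
        mu = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        diff = w - mu
        z = (diff - np.sign(diff) * 0.5) / np.sqrt(var)
        result.p_value = float(min(1.0, 2.0 * norm.sf(abs(z))))
        result.note = "normal approximation"
    result.direction = ("x_higher" if result.summary_x > result.summary_y
                        else "y_higher" if result.summary_y > result.summary_x
                        else None)
    return result


def ks_two_sample(x: Sequence[float], y: Sequence[float],
                  name: str = "ks") -> TestResult:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_x - ECDF_y|, asymptotic p."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / len(x)
    cdf_y = np.searchsorted(y, grid, side="right") / len(y)
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = len(x) * len(y) / (len(x) + len(y))
    p = float(np.clip(kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    mx, my = float(np.mean(x)), float(np.mean(y))
    return TestResult(name, d, p, n_x=len(x), n_y=len(y),
                      summary_x=mx, summary_y=my,
                      direction=("x_higher" if mx > my
                                 else "y_higher" if my > mx else None))


# -- stratified correlation structure ----------------------------------------

def stratified_correlations(fm, metadata: pd.DataFrame,
                            feature_order: Sequence[str] | None = None,
                            group_col: str = "sex",
                            method: str = "pearson",
                            min_group: int = 3) -> StratifiedCorrelations:
    """Per-group correlation matrices in one fixed feature order.

    The feature order should be the clustering order of the full cohort so
    the stratified maps are visually and positionally comparable.
    """
    data = getattr(fm, "data", fm)
    if feature_order is None:
        feature_order = list(data.columns)
    groups = {}
    for label, sub in metadata.groupby(group_col, observed=True):
        donors = [d for d in sub.index if d in data.index]
        if len(donors) < min_group:
            raise ValueError(f"group {label!r} has {len(donors)} donors, "
                             f"below the floor of {min_group}")
        corr = correlation_matrix(data.loc[donors, list(feature_order)],
                                  method=method)
        groups[str(label)] = corr
    return StratifiedCorrelations(groups, list(feature_order))


def _upper_triangle_values(R: pd.DataFrame, members: Sequence[str]) -> np.ndarray:
    sub = R.loc[list(members), list(members)].to_numpy()
    vals = sub[np.triu_indices(len(members), k=1)]
    return vals[np.isfinite(vals)]


def compare_correlation_distributions(stratified: StratifiedCorrelations,
                                      assignment: ModuleAssignment,
                                      alpha: float = 0.05
                                      ) -> tuple[TestResult, list[TestResult]]:
    """Wilcoxon comparison of pairwise R values between two groups.

    Returns the global test on all off-diagonal pairs and per-module tests
    (modules + the unassigned pool), BH-adjusted across the module family.
    Pairwise correlations are treated as exchangeable observations, as in
    the procedure this replicates; see module docstring for the caveat.
    """
    labels = stratified.group_labels
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    Ra = stratified.groups[labels[0]].R
    Rb = stratified.groups[labels[1]].R
    order = stratified.feature_order

    global_test = wilcoxon_rank_sum(
        _upper_triangle_values(Ra, order), _upper_triangle_values(Rb, order),
        name=f"global:{labels[0]}-vs-{labels[1]}")

    families = [(mid, assignment.members(mid)) for mid in assignment.module_ids]
    un = list(assignment.module_of.index[assignment.module_of == UNASSIGNED])
    if un:
        families.append((UNASSIGNED, un))
    per_module: list[TestResult] = []
    for mid, members in families:
        members = [f for f in members if f in Ra.index]
        if len(members) < 2:
            per_module.append(TestResult(f"module {mid}", float("nan"), 1.0,
                                         note="skipped: fewer than 2 members"))
            continue
        tr = wilcoxon_rank_sum(_upper_triangle_values(Ra, members),
                               _upper_triangle_values(Rb, members),
                               name=f"module {mid}")
        per_module.append(tr)
    adj = benjamini_hochberg([t.p_value for t in per_module])
    for t, a in zip(per_module, adj):
        t.adjusted_p = float(a)
    return global_test, per_module


def bootstrap_correlation_difference(fm, metadata: pd.DataFrame,
                                     group_col: str = "sex",
                                     n_boot: int = 200,
                                     seed: int = 0) -> TestResult:
    """Donor-bootstrap test of the mean pairwise-R difference between groups.

    Dependence-honest alternative to the pairwise Wilcoxon: donors are
    resampled within each group, the mean off-diagonal R difference is
    recomputed per replicate, and the p-value is the two-sided bootstrap
    probability that the difference crosses zero.
    """
    data = getattr(fm, "data", fm)
    rng = np.random.default_rng(seed)
    labels = sorted(metadata[group_col].unique())
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    donors = {g: [d for d in metadata.index[metadata[group_col] == g]
                  if d in data.index] for g in labels}

    def mean_r(d_list):
        R = correlation_matrix(data.loc[d_list]).R.to_numpy()
        return np.nanmean(R[np.triu_indices(len(R), k=1)])

    obs = mean_r(donors[labels[0]]) - mean_r(donors[labels[1]])
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        res = [rng.choice(donors[g], size=len(donors[g]), replace=True)
               for g in labels]
        diffs[b] = mean_r(list(res[0])) - mean_r(list(res[1]))
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return TestResult(f"bootstrap:{labels[0]}-vs-{labels[1]}", float(obs),
                      float(min(1.0, max(p, 1.0 / n_boot))),
                      n_x=len(donors[labels[0]]), n_y=len(donors[labels[1]]),
                      note=f"{n_boot} donor-bootstrap replicates")


def compare_module_scores(scores: pd.DataFrame, metadata: pd.DataFrame,
                          group_col: str = "sex", min_group: int = 5
                          ) -> list[TestResult]:
    """Per-module KS comparison of score distributions between two groups.

    BH adjustment runs across the module family (modules + unassigned, i.e.
    every score column); direction is reported via group means.
    """
    labels = sorted(metadata[group_col].unique())
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    donors = {g: [d for d in metadata.index[metadata[group_col] == g]
                  if d in scores.index] for g in labels}
    for g, d in donors.items():
        if len(d) < min_group:
            raise ValueError(f"group {g!r} has {len(d)} donors, "
                             f"below the floor of {min_group}")
    results = []
    for mid in scores.columns:
        a = scores.loc[donors[labels[0]], mid].dropna()
        b = scores.loc[donors[labels[1]], mid].dropna()
        tr = ks_two_sample(a, b, name=f"module {mid}")
        tr.direction = (f"{labels[0]}_higher" if tr.summary_x > tr.summary_y
                        else f"{labels[1]}_higher" if tr.summary_y > tr.summary_x
                        else None)
        results.append(tr)
    adj = benjamini_hochberg([t.p_value for t in results])
    for t, a in zip(results, adj):
        t.adjusted_p = float(a)
    return results
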