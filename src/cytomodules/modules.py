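"""Correlation-map construction and module detection.

Features are correlated pairwise across donors, hierarchically clustered on
the distance 1 - R, and the correlation map is ternarized at |R| > cutoff
into an adjacency matrix.  Modules are extracted automatically as the
maximal dendrogram clades (size >= min_size) whose positive-edge density in
the adjacency matrix reaches min_density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import log
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

UNASSIGNED = "unassigned"


@dataclass
class CorrelationMatrix:
    """Pairwise-complete feature correlations across donors."""

    R: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def features(self) -> list[str]:
        return list(self.R.columns)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    features: list[str]
    leaf_order: list[str]


@dataclass
class AdjacencyMatrix:
    """Ternary {-1, 0, +1} binning of the correlation map."""

    A: pd.DataFrame
    cutoff: float


@dataclass
class ModuleAssignment:
    """Feature -> module id ('1', '2', ... in dendrogram order) or 'unassigned'."""

    module_of: pd.Series
    min_size: int
    min_density: float

    @property
    def module_ids(self) -> list[str]:
        ids = [m for m in self.module_of.unique() if m != UNASSIGNED]
        return sorted(ids, key=int)

    def members(self, module_id: str) -> list[str]:
        return list(self.module_of.index[self.module_of == module_id])


def correlation_matrix(data: pd.DataFrame, method: str = "pearson",
                       min_pairs: int = 3) -> CorrelationMatrix:
    """Feature x feature correlation across donors (rows).

    Uses pairwise-complete observations; entries backed by fewer than
    ``min_pairs`` donors, and rows/columns of zero-variance features, are
    missing.  Accepts a raw donors x features DataFrame or a FeatureMatrix's
    ``.data``.
    """
    data = getattr(data, "data", data)
    sd = data.std(axis=0, skipna=True)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        warnings.warn(f"{len(zero_var)} zero-variance features have "
                      "undefined correlations (set missing)")
    R = data.corr(method=method, min_periods=min_pairs)
    notna = data.notna().astype(int)
    n_pairs = pd.DataFrame(notna.T.to_numpy() @ notna.to_numpy(),
                           index=data.columns, columns=data.columns)
    if zero_var:
        R.loc[zero_var, :] = np.nan
        R.loc[:, zero_var] = np.nan
    ok = [f for f in data.columns if f not in zero_var]
    diag = pd.Series(np.nan, index=data.columns)
    diag[ok] = 1.0
    np.fill_diagonal(R.values, diag.to_numpy())
    return CorrelationMatrix(R, n_pairs)


def cluster_features(corr: CorrelationMatrix,
                     linkage_method: str = "average") -> ClusterResult:
    """Agglomerative clustering on d = 1 - R (missing R treated as 0)."""
    features = corr.features
    if len(features) == 1:
        return ClusterResult(np.empty((0, 4)), features, list(features))
    D = 1.0 - corr.R.fillna(0.0).to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    condensed = D[np.triu_indices(len(features), k=1)]
    Z = hierarchy.linkage(condensed, method=linkage_method)
    order = [features[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(Z, features, order)


def bin_adjacency(corr: CorrelationMatrix, cutoff: float = 0.5) -> AdjacencyMatrix:
    """Ternarize: +1 if R > cutoff, -1 if R < -cutoff, else 0 (strict)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    R = corr.R.to_numpy()
    A = np.zeros_like(R, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        A[R > cutoff] = 1
        A[R < -cutoff] = -1
    np.fill_diagonal(A, 1)
    return AdjacencyMatrix(
        pd.DataFrame(A, index=corr.R.index, columns=corr.R.columns), cutoff)


def _positive_density(A: np.ndarray, idx: np.ndarray) -> float:
    m = len(idx)
    if m < 2:
        return 0.0
    sub = A[np.ix_(idx, idx)]
    pos = (sub == 1).sum() - m  # remove +1 diagonal
    return pos / (m * (m - 1))


def extract_modules(clust: ClusterResult, adjacency: AdjacencyMatrix,
                    min_size: int = 4, min_density: float = 0.5
                    ) -> ModuleAssignment:
    """Maximal dendrogram clades of dense positive adjacency become modules.

    A clade qualifies when it has >= min_size leaves and the fraction of
    off-diagonal within-clade pairs with adjacency +1 is >= min_density.
    Maximality: a qualifying clade is reported only if no qualifying
    ancestor exists, i.e. the top-down search stops at the first qualifying
    clade.  Features outside every qualifying clade are 'unassigned'.
    Zero-variance features (empty adjacency rows) can never satisfy the
    density rule with any partner and end up unassigned.
    """
    if min_size < 2:
        raise ValueError(f"min_size must be >= 2, got {min_size}")
    features = clust.features
    A = adjacency.A.loc[features, features].to_numpy()
    module_of = pd.Series(UNASSIGNED, index=pd.Index(features, name="feature_id"),
                          dtype=object)
    if len(features) < min_size or clust.linkage.shape[0] == 0:
        return ModuleAssignment(module_of, min_size, min_density)

    tree = hierarchy.to_tree(clust.linkage)
    found: list[list[int]] = []

    def visit(node) -> None:
        if node.get_count() < min_size:
            return
        leaves = node.pre_order(lambda x: x.id)
        if _positive_density(A, np.asarray(leaves)) >= min_density:
            found.append(leaves)
            return
        if not node.is_leaf():
            visit(node.get_left())
            visit(node.get_right())

    visit(tree)

    # Number modules by leftmost position in dendrogram display order.
    pos = {features[i]: k for k, i in
           enumerate(hierarchy.leaves_list(clust.linkage))}
    found.sort(key=lambda leaves: min(pos[features[i]] for i in leaves))
    for k, leaves in enumerate(found, start=1):
        module_of.iloc[leaves] = str(k)
    return ModuleAssignment(module_of, min_size, min_density)


def _normalized_entropy(values: Sequence[str]) -> float:
    n = len(values)
    if n <= 1:
        return 0.0
    counts = pd.Series(values).value_counts().to_numpy()
    p = counts / n
    H = -(p * np.log(p)).sum()
    return H / log(n)


def module_summary(assignment: ModuleAssignment,
                   feature_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-module attribute table: members and the dominant attribute type.

    For each module the constituent proteins, cell types and conditions are
    listed; the attribute axis with the lowest normalized entropy (most
    concentrated) is flagged as dominant, 'none' on a tie.
    """
    if not assignment.module_ids:
        raise ValueError("assignment contains no modules")
    rows = []
    attrs = ("protein", "cell_type", "condition")
    for mid in assignment.module_ids:
        members = assignment.members(mid)
        meta = feature_meta.loc[members]
        ent = {a: _normalized_entropy(list(meta[a])) for a in attrs}
        best = min(ent.values())
        winners = [a for a in attrs if abs(ent[a] - best) < 1e-12]
        rows.append({
            "module": mid,
            "n_features": len(members),
            "proteins": ";".join(sorted(meta["protein"].unique())),
            "cell_types": ";".join(sorted(meta["cell_type"].unique())),
            "conditions": ";".join(sorted(meta["condition"].unique())),
            "dominant_attribute": winners[0] if len(winners) == 1 else "none",
        })
    return pd.DataFrame(rows).set_index("module")


def within_module_correlation(corr: CorrelationMatrix,
                              assignment: ModuleAssignment
                              ) -> tuple[pd.Series, float]:
    """Mean off-diagonal R within each module, plus the all-feature mean."""
    if not assignment.module_ids:
        raise ValueError("assignment contains no modules")
    R = corr.R
    per_module = {}
    for mid in assignment.module_ids:
        members = assignment.members(mid)
        sub = R.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), k=1)
        per_module[mid] = float(np.nanmean(sub[iu])) if len(members) > 1 else np.nan
    full = R.to_numpy()
    iu = np.triu_indices(len(R), k=1)
    overall = float(np.nanmean(full[iu]))
    return pd.Series(per_module, name="mean_R"), overall
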