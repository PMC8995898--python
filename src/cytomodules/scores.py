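"""Per-donor module scores: the mean of z-normalized member features."""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .modules import UNASSIGNED, ModuleAssignment


def normalize_features(fm, method: str = "zscore"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize each feature across donors; returns (normalized, params).

    ``method='zscore'`` (default) centers/scales by cohort mean and sample
    sd; ``'minmax'`` rescales to [0, 1].  Zero-spread features are excluded
    with a warning.  The returned params frame (columns ``center``,
    ``scale``) reapplies the identical transform to new donors.
    """
    data = getattr(fm, "data", fm)
    if method == "zscore":
        center = data.mean(axis=0, skipna=True)
        scale = data.std(axis=0, ddof=1, skipna=True)
    elif method == "minmax":
        center = data.min(axis=0, skipna=True)
        scale = data.max(axis=0, skipna=True) - center
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    bad = scale.index[(scale == 0) | scale.isna()].tolist()
    if bad:
        warnings.warn(f"excluding {len(bad)} zero-spread features from "
                      "normalization")
    keep = [f for f in data.columns if f not in set(bad)]
    params = pd.DataFrame({"center": center[keep], "scale": scale[keep]})
    z = (data[keep] - center[keep]) / scale[keep]
    return z, params


def apply_normalization(data: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Apply stored normalization parameters to (possibly new) donors."""
    feats = list(params.index)
    return (data[feats] - params["center"]) / params["scale"]


def compute_module_scores(z: pd.DataFrame, assignment: ModuleAssignment,
                          include_unassigned: bool = True) -> pd.DataFrame:
    """Donors x modules score matrix: mean of member z-features per donor.

    Missing member values are ignored in the mean; a donor missing every
    member of a module gets a missing score.  Unassigned features are scored
    as their own pseudo-module when present.
    """
    groups: list[tuple[str, list[str]]] = [
        (mid, [f for f in assignment.members(mid) if f in z.columns])
        for mid in assignment.module_ids]
    if include_unassigned:
        un = [f for f in assignment.module_of.index
              if assignment.module_of[f] == UNASSIGNED and f in z.columns]
        if un:
            groups.append((UNASSIGNED, un))
    scores = {}
    for mid, members in groups:
        if not members:
            raise ValueError(f"module {mid!r} has no surviving member features")
        scores[mid] = z[members].mean(axis=1, skipna=True)
    return pd.DataFrame(scores)


def correlate_module_scores(scores: pd.DataFrame, module_a: str, module_b: str,
                            donors: Sequence[str] | None = None) -> float:
    """Pearson R between two module-score vectors over a donor subset."""
    sub = scores if donors is None else scores.loc[list(donors)]
    if len(sub) < 3:
        raise ValueError("need at least 3 donors to correlate module scores")
    a, b = sub[module_a], sub[module_b]
    if a.std(skipna=True) == 0 or b.std(skipna=True) == 0:
        warnings.warn("undefined module-score correlation (zero variance)")
        return float("nan")
    return float(a.corr(b))


def module_scores_from_features(fm: FeatureMatrix, assignment: ModuleAssignment,
                                train_donors: Sequence[str] | None = None,
                                method: str = "zscore") -> pd.DataFrame:
    """Convenience: normalize (optionally on a training subset) then score.

    When ``train_donors`` is given, normalization parameters come from those
    donors only and are applied to the whole cohort — the leakage-safe setup
    for downstream classifiers.
    """
    if train_donors is None:
        z, _ = normalize_features(fm, method=method)
    else:
        _, params = normalize_features(fm.data.loc[list(train_donors)], method=method)
        z = apply_normalization(fm.data, params)
    return compute_module_scores(z, assignment)
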