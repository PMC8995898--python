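"""Immune-feature derivation from gated cell event tables.

An immune feature is the median arcsinh-transformed intensity of one
signaling protein in one gated cell type under one stimulation condition,
minus the matched unstimulated median for the same donor.  At the default
dimensions (16 conditions x 9 cell types x 15 proteins) this enumerates
2,160 features per donor before responsiveness thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import ARCSINH_COFACTOR, CellEventTable, feature_id

DEFAULT_MIN_EVENTS = 20
DEFAULT_MIN_MEAN = 0.2


def transform_intensity(x, cofactor: float = ARCSINH_COFACTOR):
    """arcsinh(x / cofactor), the standard cytometry variance-stabilizer."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


@dataclass
class MedianTable:
    """Per-sample medians of transformed intensities, cell type x protein."""

    donor_id: str
    condition: str
    values: pd.DataFrame          # index cell_type, columns protein; NaN if too few events
    n_events: pd.Series           # events per cell type


@dataclass
class FeatureMatrix:
    """Donors x immune features with per-feature metadata.

    ``data`` rows are donors, columns feature ids ``protein|cell type|condition``;
    ``meta`` maps each feature id to its (protein, cell_type, condition).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    log: dict = field(default_factory=dict)

    @property
    def donors(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.data[list(feature_ids)].copy(),
                             self.meta.loc[list(feature_ids)].copy(),
                             dict(self.log))


def compute_sample_medians(table: CellEventTable,
                           proteins: Sequence[str],
                           cell_types: Sequence[str],
                           min_events: int = DEFAULT_MIN_EVENTS,
                           cofactor: float = ARCSINH_COFACTOR) -> MedianTable:
    """Median transformed intensity per (cell type, protein) for one sample.

    Cell types absent from the sample, or with fewer than ``min_events``
    events, yield missing entries (never zero).
    """
    events = table.events
    missing = [p for p in proteins if p not in events.columns]
    if missing:
        raise ValueError(
            f"sample {table.donor_id}/{table.condition} lacks protein "
            f"columns: {missing}")
    transformed = transform_intensity(events[list(proteins)].to_numpy(), cofactor)
    # integer label codes: avoids per-cell string comparisons on large tables
    codes, uniques = pd.factorize(events["cell_type"], use_na_sentinel=True)
    uniques = list(uniques)
    vals = np.full((len(cell_types), len(proteins)), np.nan)
    counts = np.zeros(len(cell_types), dtype=int)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    bounds = np.searchsorted(sorted_codes, np.arange(len(uniques) + 1))
    for u, label in enumerate(uniques):
        if label not in cell_types:
            continue
        i = list(cell_types).index(label)
        rows = order[bounds[u]:bounds[u + 1]]
        counts[i] = len(rows)
        if len(rows) >= min_events:
            vals[i] = np.median(transformed[rows], axis=0)
    values = pd.DataFrame(vals, index=list(cell_types), columns=list(proteins))
    return MedianTable(table.donor_id, table.condition, values,
                       pd.Series(counts, index=list(cell_types)))


def derive_features(donor_medians: Mapping[str, MedianTable],
                    unstim_condition: str,
                    conditions: Sequence[str],
                    cell_types: Sequence[str],
                    proteins: Sequence[str]) -> pd.Series:
    """Stim-minus-unstim deltas for one donor, in canonical feature order.

    The unstimulated condition is included in the enumeration (its deltas are
    exactly zero); a delta is missing if either operand median is missing.
    """
    if unstim_condition not in donor_medians:
        donor = next(iter(donor_medians.values())).donor_id if donor_medians else "?"
        raise ValueError(f"donor {donor}: no unstimulated sample "
                         f"({unstim_condition!r}) to subtract")
    unstim = donor_medians[unstim_condition].values.loc[
        list(cell_types), list(proteins)].to_numpy()
    fids: list[str] = []
    blocks: list[np.ndarray] = []
    for cond in conditions:
        fids.extend(feature_id(p, ct, cond)
                    for ct in cell_types for p in proteins)
        mt = donor_medians.get(cond)
        if mt is None:
            blocks.append(np.full(unstim.size, np.nan))
        elif cond == unstim_condition:
            blocks.append(np.where(np.isfinite(unstim), 0.0, np.nan).ravel())
        else:
            stim = mt.values.loc[list(cell_types), list(proteins)].to_numpy()
            blocks.append((stim - unstim).ravel())
    return pd.Series(np.concatenate(blocks), index=fids)


def featurize_cohort(tables: Iterable[CellEventTable],
                     conditions: Sequence[str],
                     cell_types: Sequence[str],
                     proteins: Sequence[str],
                     unstim_condition: str,
                     min_events: int = DEFAULT_MIN_EVENTS,
                     cofactor: float = ARCSINH_COFACTOR) -> FeatureMatrix:
    """Full cohort featurization: medians per sample, deltas per donor."""
    by_donor: dict[str, dict[str, MedianTable]] = {}
    for t in tables:
        mt = compute_sample_medians(t, proteins, cell_types, min_events, cofactor)
        by_donor.setdefault(t.donor_id, {})[t.condition] = mt
    rows = {donor: derive_features(meds, unstim_condition, conditions,
                                   cell_types, proteins)
            for donor, meds in by_donor.items()}
    data = pd.DataFrame(rows).T
    data.index.name = "donor_id"
    fids = [feature_id(p, ct, cond)
            for cond in conditions for ct in cell_types for p in proteins]
    data = data[fids]
    meta = pd.DataFrame(
        [(f, *f.split("|")) for f in fids],
        columns=["feature_id", "protein", "cell_type", "condition"],
    ).set_index("feature_id")
    return FeatureMatrix(data, meta)


def threshold_features(fm: FeatureMatrix,
                       min_mean: float = DEFAULT_MIN_MEAN,
                       use_absolute: bool = False) -> FeatureMatrix:
    """Keep features whose cohort mean response reaches ``min_mean`` (>=).

    The default compares the signed mean delta; set ``use_absolute`` to
    retain strong negative responders as well.
    """
    if fm.data.shape[1] == 0:
        raise ValueError("empty feature matrix")
    means = fm.data.mean(axis=0, skipna=True)
    crit = means.abs() if use_absolute else means
    keep = crit[crit >= min_mean].index.tolist()
    out = fm.subset(keep)
    out.log.update({
        "n_input": fm.data.shape[1],
        "n_retained": len(keep),
        "n_dropped": fm.data.shape[1] - len(keep),
        "min_mean": min_mean,
        "use_absolute": use_absolute,
    })
    if not keep:
        warnings.warn("thresholding dropped every feature")
    return out
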