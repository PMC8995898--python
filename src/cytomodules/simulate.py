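"""Synthetic stimulation-response cytometry cohorts with planted module structure.

The generator emulates a cohort of donors whose blood was split into aliquots,
each stimulated with one immune modulator (or left unstimulated) and profiled
by mass cytometry: per cell, one gated cell-type label and one intensity per
phospho-protein readout.

The planted statistical structure is a donor-level latent propensity per
signaling protein.  A donor's latent value is injected into the target median
of every responsive (protein, cell type, stimulus) combination, so that
donor's responses in one protein co-vary across cell types and conditions —
the mechanism behind protein-defined correlation modules.  Two orthogonal sex
knobs exist: a per-protein scaling of the latent loading (coordination
differences) and a per-protein additive mean shift (response-level
differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ARCSINH_COFACTOR = 5.0

UNSTIM = "unstim"

DEFAULT_CONDITIONS: tuple[str, ...] = (
    UNSTIM, "IFNa", "IFNb", "IFNg", "IL-2", "IL-4", "IL-6", "IL-10",
    "GM-CSF", "TNFa", "LPS", "R848", "CD40L", "PMA-iono", "anthrax", "G-CSF",
)

DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "CD4 T cells", "CD8 T cells", "B cells", "NK cells", "DCs",
    "CD14 monocytes", "CD16 monocytes", "neutrophils", "basophils",
)

DEFAULT_PROTEINS: tuple[str, ...] = (
    "pSTAT1", "pSTAT3", "pSTAT4", "pSTAT5", "pSTAT6",
    "pERK1/2", "pP38", "pCREB", "pMAPKAPK2", "pTBK1",
    "IkB", "pNFkB", "pS6", "pPLCg2", "pZAP70",
)

# Typical whole-blood composition, mildly compressed so every population
# expects >= ~30 events at 1000 cells/sample.
DEFAULT_CELL_TYPE_PROPS: dict[str, float] = {
    "CD4 T cells": 0.18,
    "CD8 T cells": 0.10,
    "B cells": 0.07,
    "NK cells": 0.07,
    "DCs": 0.03,
    "CD14 monocytes": 0.08,
    "CD16 monocytes": 0.04,
    "neutrophils": 0.40,
    "basophils": 0.03,
}

SEXES = ("F", "M")


def feature_id(protein: str, cell_type: str, condition: str) -> str:
    return f"{protein}|{cell_type}|{condition}"


def default_response_map() -> dict[tuple[str, str, str], float]:
    """Planted responses: 8 signaling-protein programs, 9-12 features each.

    Each program is one protein responding in a biologically plausible set of
    cell types under its canonical stimuli (interferons drive pSTAT1 in
    lymphocytes, TLR ligands drive MAPK/NF-kB arms in myeloid cells, ...).
    Effect sizes cycle through 0.8-1.3 on the arcsinh scale.
    """
    programs: dict[str, tuple[list[str], list[str]]] = {
        "pSTAT1": (["CD4 T cells", "CD8 T cells", "B cells", "NK cells"],
                   ["IFNa", "IFNb", "IFNg"]),
        "pSTAT5": (["CD4 T cells", "CD8 T cells", "NK cells",
                    "CD14 monocytes", "neutrophils"],
                   ["IL-2", "GM-CSF"]),
        "pSTAT6": (["B cells", "CD14 monocytes", "DCs"],
                   ["IL-4", "IFNa", "IFNb"]),
        "pERK1/2": (["CD14 monocytes", "CD16 monocytes", "neutrophils",
                     "basophils"],
                    ["PMA-iono", "GM-CSF", "LPS"]),
        "pP38": (["CD14 monocytes", "neutrophils", "basophils"],
                 ["LPS", "R848", "PMA-iono"]),
        "pCREB": (["CD14 monocytes", "neutrophils", "DCs"],
                  ["GM-CSF", "PMA-iono", "LPS"]),
        "pTBK1": (["DCs", "CD14 monocytes", "CD16 monocytes"],
                  ["LPS", "R848", "TNFa"]),
        "IkB": (["B cells", "NK cells", "CD14 monocytes", "DCs"],
                ["TNFa", "LPS", "R848"]),
    }
    effects = (0.8, 0.9, 1.0, 1.1, 1.2, 1.3)
    rmap: dict[tuple[str, str, str], float] = {}
    i = 0
    for protein, (cts, conds) in programs.items():
        for ct in cts:
            for cond in conds:
                rmap[(protein, ct, cond)] = effects[i % len(effects)]
                i += 1
    return rmap


@dataclass
class SimConfig:
    """Cohort-generator configuration; defaults are the study conditions."""

    n_donors: int = 86
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    unstim_condition: str = UNSTIM
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    proteins: tuple[str, ...] = DEFAULT_PROTEINS
    cells_per_sample: int = 1000
    response_map: dict[tuple[str, str, str], float] = field(
        default_factory=default_response_map)
    loading_by_sex: dict[str, float | Mapping[str, float]] = field(
        default_factory=lambda: {"F": 1.0, "M": 1.0})
    mean_shift_by_sex: dict[str, Mapping[str, float]] = field(
        default_factory=lambda: {"F": {}, "M": {}})
    cell_noise_sd: float = 0.25
    sample_noise_sd: float = 0.46
    cell_type_props: Mapping[str, float] | None = None
    dirichlet_concentration: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_donors", "cells_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("cell_noise_sd", "sample_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, "
                                 f"got {getattr(self, name)}")
        if self.unstim_condition not in self.conditions:
            raise ValueError(
                f"unstim_condition {self.unstim_condition!r} not in conditions")
        if sum(c == self.unstim_condition for c in self.conditions) != 1:
            raise ValueError("exactly one condition must be the unstimulated reference")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique")
        for (p, ct, cond), eff in self.response_map.items():
            if not math.isfinite(eff):
                raise ValueError(f"non-finite effect for {(p, ct, cond)}")
            if p not in self.proteins or ct not in self.cell_types \
                    or cond not in self.conditions:
                raise ValueError(f"response_map triple {(p, ct, cond)} outside "
                                 "configured proteins/cell_types/conditions")
            if cond == self.unstim_condition:
                raise ValueError("response_map may not target the unstimulated condition")
        for sex in self.loading_by_sex:
            if sex not in SEXES:
                raise ValueError(f"unknown sex label {sex!r} in loading_by_sex")
        if self.cell_type_props is None:
            if tuple(self.cell_types) == DEFAULT_CELL_TYPES:
                self.cell_type_props = dict(DEFAULT_CELL_TYPE_PROPS)
            else:
                self.cell_type_props = {
                    ct: 1.0 / len(self.cell_types) for ct in self.cell_types}

    # -- planted-parameter lookups ------------------------------------------

    def loading_vector(self, sex: str) -> np.ndarray:
        """Latent-factor loading per protein for one sex."""
        if sex not in self.loading_by_sex:
            raise ValueError(f"unknown sex label {sex!r}")
        spec = self.loading_by_sex[sex]
        if isinstance(spec, Mapping):
            return np.array([float(spec.get(p, 1.0)) for p in self.proteins])
        return np.full(len(self.proteins), float(spec))

    def shift_vector(self, sex: str) -> np.ndarray:
        """Additive mean shift per protein for one sex (responsive features only)."""
        spec = self.mean_shift_by_sex.get(sex, {})
        return np.array([float(spec.get(p, 0.0)) for p in self.proteins])

    def feature_ids(self) -> list[str]:
        """All features in canonical (condition, cell type, protein) order."""
        return [feature_id(p, ct, cond)
                for cond in self.conditions
                for ct in self.cell_types
                for p in self.proteins]


@dataclass
class CellEventTable:
    """Per-(donor, condition) event table: cell_type label + raw intensities."""

    donor_id: str
    condition: str
    events: pd.DataFrame  # columns: cell_type, then one column per protein


@dataclass
class GroundTruth:
    """Simulator-side oracle for recovery tests."""

    module_of_feature: pd.Series          # feature id -> protein module / "unassigned"
    donor_latents: pd.DataFrame           # donors x proteins
    sex_effect_features: dict[str, list[str]]  # "male_higher"/"female_higher"


def sample_donor_latents(config: SimConfig, sex: str,
                         rng: np.random.Generator) -> np.ndarray:
    """One standard-normal latent propensity per protein for a new donor.

    The sex-specific loading is applied where the latent enters feature
    means, not here; this draw is the donor's intrinsic propensity.
    """
    if sex not in config.loading_by_sex:
        raise ValueError(f"unknown sex label {sex!r}")
    return rng.standard_normal(len(config.proteins))


def truth_modules(config: SimConfig) -> pd.Series:
    """Ground-truth module label per enumerated feature.

    Responsive features carry their protein's name as the module id;
    everything else is "unassigned".
    """
    responsive = {feature_id(*k): k[0] for k in config.response_map}
    ids = config.feature_ids()
    return pd.Series([responsive.get(f, "unassigned") for f in ids],
                     index=ids, name="module", dtype=object)


def _baseline_matrix(config: SimConfig) -> np.ndarray:
    """Deterministic basal arcsinh-scale level per (cell type, protein)."""
    n_ct, n_p = len(config.cell_types), len(config.proteins)
    i = np.arange(n_ct)[:, None]
    j = np.arange(n_p)[None, :]
    return 0.3 + 0.4 * ((i + 2 * j) % 7) / 7.0


def generate_cohort(config: SimConfig
                    ) -> tuple[list[CellEventTable], pd.DataFrame, GroundTruth]:
    """Simulate one cohort: event tables, donor metadata, and ground truth.

    Returns one :class:`CellEventTable` per (donor, condition).  Raw
    intensities are ``cofactor * sinh(transformed)`` so the featurizer's
    arcsinh transform inverts the construction exactly.  Fully reproducible
    under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_d = config.n_donors
    conds = list(config.conditions)
    cts = list(config.cell_types)
    prots = list(config.proteins)
    n_c, n_ct, n_p = len(conds), len(cts), len(prots)

    donor_ids = [f"D{i + 1:03d}" for i in range(n_d)]
    sexes = np.array((["F", "M"] * ((n_d + 1) // 2))[:n_d])
    rng.shuffle(sexes)
    ages = rng.integers(19, 66, size=n_d)
    metadata = pd.DataFrame(
        {"donor_id": donor_ids, "sex": sexes, "age": ages}).set_index("donor_id")

    latents = np.vstack([sample_donor_latents(config, s, rng) for s in sexes])

    # Responsive-triple masks/effects on the (condition, cell type, protein) grid.
    effect = np.zeros((n_c, n_ct, n_p))
    responsive = np.zeros((n_c, n_ct, n_p), dtype=bool)
    ci = {c: i for i, c in enumerate(conds)}
    ti = {t: i for i, t in enumerate(cts)}
    pi = {p: i for i, p in enumerate(prots)}
    for (p, ct, cond), eff in config.response_map.items():
        effect[ci[cond], ti[ct], pi[p]] = eff
        responsive[ci[cond], ti[ct], pi[p]] = True

    base = _baseline_matrix(config)                      # (ct, p)
    zeta = rng.normal(0.0, config.sample_noise_sd,
                      size=(n_d, n_c, n_ct, n_p))        # per-sample variation

    base_props = np.array([config.cell_type_props[ct] for ct in cts], float)
    base_props = base_props / base_props.sum()
    conc = config.dirichlet_concentration

    loadings = {s: config.loading_vector(s) for s in SEXES}
    shifts = {s: config.shift_vector(s) for s in SEXES}

    tables: list[CellEventTable] = []
    for d in range(n_d):
        sex = sexes[d]
        donor_component = loadings[sex] * latents[d] + shifts[sex]   # (p,)
        for c in range(n_c):
            # Target median on the transformed scale per (cell type, protein).
            target = base + zeta[d, c]
            target = target + responsive[c] * (effect[c] + donor_component[None, :])
            props = rng.dirichlet(conc * base_props)
            counts = rng.multinomial(config.cells_per_sample, props)
            ct_idx = np.repeat(np.arange(n_ct), counts)
            transformed = target[ct_idx] + rng.normal(
                0.0, config.cell_noise_sd, size=(len(ct_idx), n_p))
            raw = ARCSINH_COFACTOR * np.sinh(transformed)
            events = pd.DataFrame(raw, columns=prots)
            events.insert(0, "cell_type", pd.Categorical(
                [cts[i] for i in ct_idx], categories=cts))
            tables.append(CellEventTable(donor_ids[d], conds[c], events))

    truth = GroundTruth(
        module_of_feature=truth_modules(config),
        donor_latents=pd.DataFrame(latents, index=donor_ids, columns=prots),
        sex_effect_features=_sex_effect_features(config),
    )
    return tables, metadata, truth


def _sex_effect_features(config: SimConfig) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {"male_higher": [], "female_higher": []}
    shift_f = dict(config.mean_shift_by_sex.get("F", {}))
    shift_m = dict(config.mean_shift_by_sex.get("M", {}))
    for (p, ct, cond) in config.response_map:
        net = shift_f.get(p, 0.0) - shift_m.get(p, 0.0)
        if net > 0:
            out["female_higher"].append(feature_id(p, ct, cond))
        elif net < 0:
            out["male_higher"].append(feature_id(p, ct, cond))
    return out


# -- named study conditions --------------------------------------------------

def sex_coordination_config(seed: int = 0, strong: float = 1.4,
                            weak: float = 0.6) -> SimConfig:
    """Cohort with female-higher signaling coordination in 6 of 8 programs.

    Females carry a stronger latent loading (default 1.4 vs 0.6) for the
    pSTAT1/pSTAT5/pSTAT6/pERK1/2/pP38/pCREB programs; pTBK1 and IkB stay
    sex-neutral.  Means are untouched, so only correlation structure differs.
    """
    coord = ("pSTAT1", "pSTAT5", "pSTAT6", "pERK1/2", "pP38", "pCREB")
    return SimConfig(
        loading_by_sex={"F": {p: strong for p in coord},
                        "M": {p: weak for p in coord}},
        seed=seed)


SEX_SHIFT_MALE_PROTEINS = ("pSTAT1", "pTBK1")
SEX_SHIFT_FEMALE_PROTEINS = ("pERK1/2", "pP38", "pCREB")


def sex_shift_config(seed: int = 0, shift: float = 0.8) -> SimConfig:
    """Cohort with sex-shifted mean responses by protein program.

    Males respond higher in interferon/TBK arms (pSTAT1, pTBK1), females in
    the MAPK/CREB inflammatory arms (pERK1/2, pP38, pCREB); shift is on the
    arcsinh scale and applies to responsive features of those proteins.
    """
    return SimConfig(
        mean_shift_by_sex={
            "M": {p: shift for p in SEX_SHIFT_MALE_PROTEINS},
            "F": {p: shift for p in SEX_SHIFT_FEMALE_PROTEINS},
        },
        seed=seed)
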