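"""Shared fixtures: small, fast synthetic cohorts for unit tests."""

from __future__ import annotations

import pytest

from cytomodules import (SimConfig, featurize_cohort, generate_cohort,
                         threshold_features)

SMALL_PROTEINS = ("pSTAT1", "pERK1/2", "pP38", "pTBK1", "pCREB")
SMALL_CELL_TYPES = ("T cells", "monocytes", "NK cells")
SMALL_CONDITIONS = ("unstim", "IFNa", "LPS", "PMA-iono", "GM-CSF")


def small_response_map() -> dict:
    """Two planted programs (pSTAT1, pERK1/2) of 6 features each."""
    rmap = {}
    for ct in SMALL_CELL_TYPES:
        for cond in ("IFNa", "LPS"):
            rmap[("pSTAT1", ct, cond)] = 1.0
        for cond in ("PMA-iono", "GM-CSF"):
            rmap[("pERK1/2", ct, cond)] = 1.2
    return rmap


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_donors=40,
        conditions=SMALL_CONDITIONS,
        cell_types=SMALL_CELL_TYPES,
        proteins=SMALL_PROTEINS,
        cells_per_sample=250,
        response_map=small_response_map(),
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    tables, metadata, truth = generate_cohort(cfg)
    return cfg, tables, metadata, truth


@pytest.fixture(scope="session")
def small_features(small_cohort):
    cfg, tables, metadata, truth = small_cohort
    fm = featurize_cohort(tables, cfg.conditions, cfg.cell_types,
                          cfg.proteins, cfg.unstim_condition)
    return cfg, fm, threshold_features(fm), metadata, truth
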