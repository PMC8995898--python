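"""Reading and writing pipeline artifacts (CSV matrices + JSON sidecars)."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig, config_to_dict
from .features import FeatureMatrix
from .modules import AdjacencyMatrix, CorrelationMatrix, ModuleAssignment
from .simulate import CellEventTable

logger = logging.getLogger("cytomodules")

MANIFEST_NAME = "events_manifest.csv"


def write_event_tables(tables: Iterable[CellEventTable], out_dir: str | Path,
                       metadata: pd.DataFrame | None = None) -> Path:
    """One CSV per (donor, condition) plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tables:
        cond_safe = t.condition.replace("/", "-")
        fname = f"{t.donor_id}__{cond_safe}.csv"
        t.events.to_csv(out_dir / fname, index=False)
        rows.append({"donor_id": t.donor_id, "condition": t.condition,
                     "path": fname})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / MANIFEST_NAME, index=False)
    if metadata is not None:
        metadata.to_csv(out_dir / "donor_metadata.csv")
    return out_dir / MANIFEST_NAME


def read_event_tables(manifest_path: str | Path,
                      required_columns: Sequence[str] | None = None
                      ) -> list[CellEventTable]:
    """Load event tables listed in a manifest (or a directory holding one).

    Extra columns in an event CSV are kept and logged; a missing required
    column raises an error naming the file and the column.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    for col in ("donor_id", "condition", "path"):
        if col not in manifest.columns:
            raise ValueError(f"manifest {manifest_path} lacks column {col!r}")
    base = manifest_path.parent
    tables = []
    for _, row in manifest.iterrows():
        fpath = base / row["path"]
        if not fpath.exists():
            raise FileNotFoundError(f"event table missing: {fpath}")
        events = pd.read_csv(fpath)
        if "cell_type" not in events.columns:
            raise ValueError(f"{fpath} lacks column 'cell_type'")
        if required_columns:
            missing = [c for c in required_columns if c not in events.columns]
            if missing:
                raise ValueError(f"{fpath} lacks column(s) {missing}")
            extras = [c for c in events.columns
                      if c not in ("cell_type", *required_columns)]
            if extras:
                logger.info("%s: ignoring extra column(s) %s", fpath, extras)
        tables.append(CellEventTable(str(row["donor_id"]),
                                     str(row["condition"]), events))
    return tables


def write_feature_matrix(fm: FeatureMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    fm.data.to_csv(f"{prefix}.csv")
    fm.meta.reset_index().to_json(f"{prefix}.meta.json", orient="records",
                                  indent=1)


def read_feature_matrix(prefix: str | Path) -> FeatureMatrix:
    prefix = Path(prefix)
    data = pd.read_csv(f"{prefix}.csv", index_col=0)
    meta = pd.read_json(f"{prefix}.meta.json", orient="records"
                        ).set_index("feature_id")
    meta = meta.loc[data.columns]
    meta.index.name = "feature_id"
    return FeatureMatrix(data, meta)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_results(result, out_dir: str | Path) -> list[Path]:
    """Persist a PipelineResult's artifacts; returns the files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise NotADirectoryError(out_dir)
    written: list[Path] = []

    def _csv(df: pd.DataFrame, name: str, **kw) -> None:
        path = out_dir / name
        df.to_csv(path, **kw)
        written.append(path)

    def _json(payload, name: str) -> None:
        path = out_dir / name
        path.write_text(json.dumps(payload, indent=1, default=_jsonable))
        written.append(path)

    if result.metadata is not None:
        _csv(result.metadata, "donor_metadata.csv")
    if result.features_raw is not None:
        write_feature_matrix(result.features_raw, out_dir / "features_raw")
        written += [out_dir / "features_raw.csv", out_dir / "features_raw.meta.json"]
    if result.features is not None:
        write_feature_matrix(result.features, out_dir / "features")
        written += [out_dir / "features.csv", out_dir / "features.meta.json"]
    if result.correlation is not None:
        _csv(result.correlation.R, "correlation.csv")
    if result.adjacency is not None:
        _csv(result.adjacency.A, "adjacency.csv")
    if result.assignment is not None:
        _csv(result.assignment.module_of.rename("module").to_frame(),
             "modules.csv")
    if result.summary is not None:
        _csv(result.summary, "module_summary.csv")
    if result.scores is not None:
        _csv(result.scores, "module_scores.csv")
    if result.stat_tests:
        _json(result.stat_tests, "stat_tests.json")
    if result.sam is not None:
        _csv(pd.DataFrame({"d": result.sam.d, "q": result.sam.q,
                           "s": result.sam.s}), "sam.csv")
    if result.model_results:
        _json({name: {"accuracy": r["evaluation"]["accuracy"],
                      "auc": r["evaluation"]["auc"],
                      "selected": r["fit"].selected,
                      "lambda": r["fit"].spec.lam,
                      "alpha": r["fit"].spec.alpha,
                      "kind": r["fit"].spec.kind}
               for name, r in result.model_results.items()}, "models.json")
    _json({"config_hash": _config_hash(result.config),
           "seed": result.config.seed,
           "timings_s": result.timings}, "run_manifest.json")
    return written


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items()
                if not isinstance(v, (pd.DataFrame, np.ndarray))}
    return str(obj)
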