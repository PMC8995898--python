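"""Pipeline configuration: schema-validated nested blocks, YAML/JSON-loadable."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimConfig


@dataclass
class FeaturizerConfig:
    cofactor: float = 5.0
    min_mean: float = 0.2
    min_events: int = 20
    use_absolute: bool = False


@dataclass
class ModuleConfig:
    cutoff: float = 0.5
    linkage: str = "average"
    min_size: int = 4
    min_density: float = 0.5
    correlation_method: str = "pearson"

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must be in (0, 1), got {self.cutoff}")


@dataclass
class StatsConfig:
    n_perm: int = 1000
    fdr: float = 0.01
    alpha: float = 0.05


@dataclass
class ModelConfig:
    enabled: bool = True
    n_train: int = 50
    k: int = 10
    repeats: int = 3
    n_lambda: int = 20
    sgl_alpha: float = 0.5


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    featurizer: FeaturizerConfig = field(default_factory=FeaturizerConfig)
    module: ModuleConfig = field(default_factory=ModuleConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    run_stats: bool = True

    def replace_seed(self, seed: int) -> "PipelineConfig":
        sim = dataclasses.replace(self.sim, seed=seed)
        return dataclasses.replace(self, sim=sim, seed=seed)


_BLOCKS = {
    "sim": SimConfig,
    "featurizer": FeaturizerConfig,
    "module": ModuleConfig,
    "stats": StatsConfig,
    "model": ModelConfig,
}


def _build(cls, payload: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config "
                         f"block {path!r}")
    kwargs = dict(payload)
    if cls is SimConfig:
        for key in ("conditions", "cell_types", "proteins"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "response_map" in kwargs and isinstance(kwargs["response_map"], list):
            kwargs["response_map"] = {
                (e["protein"], e["cell_type"], e["condition"]): float(e["effect"])
                for e in kwargs["response_map"]}
    return cls(**kwargs)


def config_from_dict(payload: dict) -> PipelineConfig:
    """Build a validated PipelineConfig; unknown keys anywhere are rejected."""
    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - top_names
    if unknown:
        raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in payload.items():
        if key in _BLOCKS:
            kwargs[key] = _build(_BLOCKS[key], dict(value), key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON pipeline configuration file."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(payload or {})


def config_to_dict(config: PipelineConfig) -> dict:
    out = dataclasses.asdict(config)
    rmap = out["sim"].pop("response_map")
    out["sim"]["response_map"] = [
        {"protein": p, "cell_type": ct, "condition": c, "effect": e}
        for (p, ct, c), e in rmap.items()]
    return out
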