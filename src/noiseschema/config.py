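"""Run configuration: validated, serializable, seed-explicit.

A RunConfig bundles every knob of a pipeline run (front end, observer
windows, experiment descriptor, analysis sizes) plus a single master seed
that fans out to per-stage seeds through a documented splitting rule
(``stage_seed``).  Unknown keys are rejected with their names listed.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .detector import WindowConfig
from .frontend import FrontendConfig


class ConfigError(ValueError):
    pass


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed.

    Combines the master seed with a CRC32 of the stage name through a
    SeedSequence, folded below 2**31.
    """
    h = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0] % 2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


@dataclass
class ExperimentSettings:
    name: str = "exp1"
    n_backgrounds: int = 40
    mod_depth: tuple = (0.4, 0.8)   # scalar, or a (lo, hi) range per background
    event_density: float = 0.0


@dataclass
class AnalysisSettings:
    q: float = 0.99
    threshold_mode: str = "trial"
    n_calibration: int = 100
    n_boot: int = 1000
    n_perm: int = 1000


@dataclass
class RunConfig:
    frontend: FrontendConfig = field(default_factory=FrontendConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    experiment: ExperimentSettings = field(default_factory=ExperimentSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    seed: int = 0


_SECTIONS = {
    "frontend": FrontendConfig,
    "window": WindowConfig,
    "experiment": ExperimentSettings,
    "analysis": AnalysisSettings,
}


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"unknown keys in section '{section}': {sorted(unknown)}"
        )
    # tuples for list-valued fields so configs round-trip to hashable values
    data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a YAML/JSON config; missing keys take the model defaults
    (past 1,000 ms / present 500 ms windows)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    seed = data.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError("seed must be a nonnegative integer")
    return RunConfig(seed=seed, **kwargs)


def dump_config(cfg: RunConfig, path) -> None:
    """Serialize a RunConfig to YAML (round-trips through load_config)."""
    def section(obj):
        out = {}
        for f in dataclasses.fields(obj):
            if not f.init:
                continue
            v = getattr(obj, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    data = {name: section(getattr(cfg, name)) for name in _SECTIONS}
    data["seed"] = cfg.seed
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
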