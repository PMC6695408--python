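"""Scenario configuration files and run manifests.

A scenario config is a small YAML document naming the horizon, agent
count, master seed and the CSV parameter tables; a run manifest records
the seeds, SHA-256 hashes of every input and the package version, enough
to reproduce a run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import yaml

from . import __version__
from .interventions import InterventionSpec, get_preset
from .population import read_entry_schedule, read_population_distribution
from .progression import (
    ModelSet,
    SimulationSettings,
    read_bmi_drift,
    read_diabetic_mortality,
    read_life_table,
    read_tpms,
)

__all__ = ["ScenarioConfig", "ConfigError", "load_config", "write_manifest"]

_REQUIRED_INPUTS = ("population_distribution", "life_table", "diabetic_mortality", "bmi_drift", "tpms")


class ConfigError(ValueError):
    """Invalid or incomplete scenario configuration; names the field."""


@dataclass
class ScenarioConfig:
    path: Path
    start_year: int
    horizon: int
    n_agents: int
    agent_scale: float
    master_seed: int
    bmi_floor: float
    per_case_benefit: float
    discount_rate: float
    inputs: Dict[str, Path]
    intervention: Optional[str] = None
    age_lo: Optional[int] = None
    age_hi: Optional[int] = None

    def intervention_spec(self) -> Optional[InterventionSpec]:
        if self.intervention is None:
            return None
        return get_preset(self.intervention, self.age_lo, self.age_hi)

    def load_models(self) -> tuple:
        """Read all parameter tables; returns (models, dist, settings)."""
        models = ModelSet(
            life_table=read_life_table(self.inputs["life_table"]),
            diabetic_mortality=read_diabetic_mortality(self.inputs["diabetic_mortality"]),
            bmi_drift=read_bmi_drift(self.inputs["bmi_drift"]),
            tpms=read_tpms(self.inputs["tpms"]),
        )
        dist = read_population_distribution(self.inputs["population_distribution"])
        schedule = None
        if "entry_schedule" in self.inputs:
            schedule = read_entry_schedule(self.inputs["entry_schedule"])
        settings = SimulationSettings(
            horizon=self.horizon,
            start_year=self.start_year,
            agent_scale=self.agent_scale,
            bmi_floor=self.bmi_floor,
            entry_schedule=schedule,
        )
        return models, dist, settings


def load_config(path) -> ScenarioConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")

    def req(key, cast, default=None):
        if key not in raw:
            if default is not None:
                return default
            raise ConfigError(f"config field missing: {key!r}")
        try:
            return cast(raw[key])
        except (TypeError, ValueError):
            raise ConfigError(f"config field invalid: {key!r}={raw[key]!r}") from None

    horizon = req("horizon", int)
    if horizon < 0:
        raise ConfigError("config field invalid: 'horizon' must be >= 0")
    n_agents = req("n_agents", int)
    if n_agents < 1:
        raise ConfigError("config field invalid: 'n_agents' must be >= 1")

    inputs_raw = raw.get("inputs")
    if not isinstance(inputs_raw, dict):
        raise ConfigError("config field missing: 'inputs'")
    inputs: Dict[str, Path] = {}
    for name in _REQUIRED_INPUTS:
        if name not in inputs_raw:
            raise ConfigError(f"config field missing: 'inputs.{name}'")
    for name, p in inputs_raw.items():
        p = (path.parent / p).resolve() if not Path(p).is_absolute() else Path(p)
        inputs[name] = p

    interv = raw.get("intervention") or {}
    if interv and not isinstance(interv, dict):
        raise ConfigError("config field invalid: 'intervention' must be a mapping")

    return ScenarioConfig(
        path=path,
        start_year=req("start_year", int, 2010),
        horizon=horizon,
        n_agents=n_agents,
        agent_scale=req("agent_scale", float, 1.0),
        master_seed=req("master_seed", int, 0),
        bmi_floor=req("bmi_floor", float, 15.0),
        per_case_benefit=req("per_case_benefit", float, 85_200.0),
        discount_rate=req("discount_rate", float, 0.0),
        inputs=inputs,
        intervention=interv.get("preset"),
        age_lo=interv.get("age_lo"),
        age_hi=interv.get("age_hi"),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(config: ScenarioConfig, out_path, extra: Optional[dict] = None) -> dict:
    """Write the reproducibility manifest next to a run output."""
    manifest = {
        "package": "prediasim",
        "version": __version__,
        "master_seed": config.master_seed,
        "start_year": config.start_year,
        "horizon": config.horizon,
        "n_agents": config.n_agents,
        "agent_scale": config.agent_scale,
        "config_sha256": _sha256(config.path),
        "inputs": {name: _sha256(p) for name, p in sorted(config.inputs.items())},
    }
    if extra:
        manifest.update(extra)
    Path(out_path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
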