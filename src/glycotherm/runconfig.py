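"""Run configuration: one YAML document wiring model, thermodynamics, reactor,
scenario and analysis settings together, plus provenance-stamped output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .kinetic_core import NetworkModel
from .modelio import load_model, load_packaged_model
from .reactor import ReactorConfig
from .scenarios import ScenarioSpec
from .synthetic_data import NoiseModel
from .thermo import RatkowskyParams, SensitivitySpec


@dataclass
class AnalysisConfig:
    theta: float = 0.15
    permutations: int = 1000
    seed: int = 0


@dataclass
class RunConfig:
    """Fully resolved configuration of one run."""

    model: NetworkModel
    ratkowsky: RatkowskyParams
    sensitivity: SensitivitySpec | None
    keq_temperature_dependence: bool
    reactor: ReactorConfig
    scenarios: list[ScenarioSpec]
    noise: NoiseModel
    analysis: AnalysisConfig
    output_dir: Path
    config_hash: str = ""
    source: str = ""

    @property
    def hypothesis(self) -> str:
        return "single_enzyme_different" if self.sensitivity else "identical"


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = path.read_bytes()
    doc = yaml.safe_load(raw) or {}
    known = {"model", "thermo", "reactor", "scenarios", "noise", "analysis",
             "output_dir"}
    bad = set(doc) - known
    if bad:
        raise ConfigurationError(f"unknown config keys: {sorted(bad)}")

    model_entry = doc.get("model", "packaged:reduced_glycolysis")
    if isinstance(model_entry, str) and model_entry.startswith("packaged:"):
        model = load_packaged_model(model_entry.split(":", 1)[1])
    else:
        model_path = Path(model_entry)
        if not model_path.is_absolute():
            model_path = path.parent / model_path
        if not model_path.exists():
            raise ConfigurationError(f"model file not found: {model_path}")
        model = load_model(model_path)

    thermo_doc = doc.get("thermo", {})
    ratkowsky = RatkowskyParams(**thermo_doc.get("ratkowsky", {}))
    sens_doc = thermo_doc.get("sensitivity")
    sensitivity = SensitivitySpec(**sens_doc) if sens_doc else None
    keq_flag = bool(thermo_doc.get("keq_temperature_dependence", False))

    reactor = ReactorConfig(**doc.get("reactor", {}))
    scen_docs = doc.get("scenarios", [{"regime": "SBR"}])
    scenarios = []
    for sd in scen_docs:
        sd = dict(sd)
        if sensitivity is not None:
            sd.setdefault("hypothesis", "single_enzyme_different")
        spec = ScenarioSpec(sensitivity=sensitivity, **sd)
        scenarios.append(spec)
    noise = NoiseModel(**doc.get("noise", {}))
    analysis = AnalysisConfig(**doc.get("analysis", {}))
    out_dir = Path(doc.get("output_dir", "results"))
    if not out_dir.is_absolute():
        out_dir = path.parent / out_dir
    return RunConfig(model=model, ratkowsky=ratkowsky, sensitivity=sensitivity,
                     keq_temperature_dependence=keq_flag, reactor=reactor,
                     scenarios=scenarios, noise=noise, analysis=analysis,
                     output_dir=out_dir,
                     config_hash=hashlib.sha256(raw).hexdigest()[:16],
                     source=str(path))


def provenance(config: RunConfig | None = None, seed: int | None = None) -> dict:
    out = {"package": "glycotherm", "version": __version__}
    if config is not None:
        out["config_hash"] = config.config_hash
        out["config"] = config.source
    if seed is not None:
        out["seed"] = seed
    return out


def write_table(df: pd.DataFrame, path: str | Path,
                prov: dict | None = None) -> None:
    """CSV with a provenance sidecar JSON (fixed dialect: comma, '.' decimal,
    UTF-8, header row)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    if prov is not None:
        path.with_suffix(path.suffix + ".prov.json").write_text(
            json.dumps(prov, indent=1))
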