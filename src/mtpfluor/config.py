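"""Run configuration: structured text (YAML/JSON) with full default echo.

Every run resolves the configuration against the documented defaults,
serialises the result to the output directory (``runconfig.json``) and
records a content hash so downstream outputs are traceable to the exact
settings that produced them.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .preprocess import PreprocessConfig
from .synth.experiment import OfflineNoise
from .synth.kinetics import KineticParams
from .synth.spectra import SpectralModel, default_spectral_model
from .validate import SplitConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    seed: int = 42
    out_dir: str = "out"
    em_step: float = 2.0  # nm; 0.45 restores the canonical emission grid
    n_replicates: int = 2
    spectral_noise: bool = True
    horizon: float = 25.0
    n_lv: int | str = 2  # integer or "auto"
    max_lv: int = 6
    kinetics: dict = field(default_factory=dict)
    spectral: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)

    def kinetic_params(self) -> KineticParams:
        return KineticParams(**self.kinetics)

    def spectral_model(self) -> SpectralModel:
        return default_spectral_model(**self.spectral)

    def offline_noise(self) -> OfflineNoise | None:
        if self.noise.get("offline") is False:
            return None
        d = {k: v for k, v in self.noise.items() if k in ("glycerol", "cdw", "ph")}
        return OfflineNoise(**d)

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(**self.preprocess)

    def split_config(self) -> SplitConfig:
        d = dict(self.split)
        d.setdefault("horizon", self.horizon)
        if "calibration_conditions" in d:
            d["calibration_conditions"] = tuple(d["calibration_conditions"])
        if d.get("prediction_conditions") is not None:
            d["prediction_conditions"] = tuple(d["prediction_conditions"])
        return SplitConfig(**d)

    def resolved(self) -> dict:
        """Fully resolved settings, defaults echoed."""
        d = dataclasses.asdict(self)
        d["kinetics"] = dataclasses.asdict(self.kinetic_params())
        model = self.spectral_model()
        d["spectral"] = {
            **{
                k: getattr(model, k)
                for k in (
                    "scatter_gain", "scatter_sat", "scatter_width", "noise_add_sd",
                    "noise_mult_sd", "well_gain_sd", "early_artifact_amp",
                )
            },
            "components": [dataclasses.asdict(b) for b in model.components],
        }
        noise = self.offline_noise()
        d["noise"] = None if noise is None else dataclasses.asdict(noise)
        d["preprocess"] = dataclasses.asdict(self.preprocess_config())
        d["split"] = dataclasses.asdict(self.split_config())
        return d


def config_hash(resolved: dict) -> str:
    return hashlib.sha256(json.dumps(resolved, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load YAML/JSON config (YAML is a JSON superset here) plus overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def write_run_log(cfg: RunConfig, out_dir: str | Path) -> str:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = cfg.resolved()
    h = config_hash(resolved)
    (out_dir / "runconfig.json").write_text(
        json.dumps({"config_hash": h, "resolved": resolved}, indent=1)
    )
    return h
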