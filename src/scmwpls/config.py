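"""Run configuration: one YAML file with full defaulting.

Every pipeline parameter has the study default, so an empty file (or no
file) reproduces the standard analysis: 11,536-3,952 cm^-1 axis at 8 cm^-1,
saturated 5,248-4,984 cm^-1 band excluded, Savitzky-Golay second derivative
(window 7, order 2), moving window of 20 channels, 10 latent variables
maximum, exhaustive sub-window search.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grid import RegionSet
from .pipeline import AnalysisConfig
from .preprocess import PreprocessSpec

__all__ = ["RunConfig", "load_config"]

_DEFAULTS: dict = {
    "grid": {"high_cm1": 11536.0, "low_cm1": 3952.0, "step_cm1": 8.0},
    "exclusions": "5248-4984",
    "preprocess": {
        "method": "second_derivative",
        "sg_window_points": 7,
        "sg_polyorder": 2,
        "edge_policy": "trim",
    },
    "mwplsr": {"window_size": 20, "k_max": 10},
    "detection": {"lv_ref": 3, "quantile_threshold": 0.15, "min_run": 3},
    "scmwpls": {
        "order_policy": "wavenumber",
        "w_min": 1,
        "w_max": None,
        "stride": 1,
        "rel_improvement": 0.02,
    },
    "evaluation": {"alpha": 0.05, "n_effective": None},
    "analyte": "ethanol",
    "seed": 0,
    "paths": {"output_dir": "scmwpls_out"},
    "manual_regions": None,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    raw: dict = field(default_factory=lambda: dict(_DEFAULTS))

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def analyte(self) -> str:
        return self.raw["analyte"]

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["paths"]["output_dir"])

    def analysis_config(self) -> AnalysisConfig:
        r = self.raw
        return AnalysisConfig(
            exclusions=RegionSet.from_string(r["exclusions"]) if r["exclusions"] else RegionSet([]),
            preprocess=PreprocessSpec.from_dict(r["preprocess"]),
            window_size=r["mwplsr"]["window_size"],
            k_max=r["mwplsr"]["k_max"],
            lv_ref=r["detection"]["lv_ref"],
            quantile_threshold=r["detection"]["quantile_threshold"],
            min_run=r["detection"]["min_run"],
            order_policy=r["scmwpls"]["order_policy"],
            w_min=r["scmwpls"]["w_min"],
            w_max=r["scmwpls"]["w_max"],
            stride=r["scmwpls"]["stride"],
            rel_improvement=r["scmwpls"]["rel_improvement"],
            alpha=r["evaluation"]["alpha"],
            n_effective=r["evaluation"]["n_effective"],
            manual_regions=(
                RegionSet.from_string(r["manual_regions"])
                if r["manual_regions"]
                else None
            ),
        )

    def config_hash(self) -> str:
        """Short digest embedded in every output file for provenance."""
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stamp(self) -> str:
        return f"# config={self.config_hash()} seed={self.seed}"


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config (missing keys take defaults); keyword overrides
    win over the file."""
    raw = dict(_DEFAULTS)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        raw = _deep_merge(raw, loaded)
    raw = _deep_merge(raw, {k: v for k, v in overrides.items() if v is not None})
    return RunConfig(raw)
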