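"""YAML configuration loading for pipeline runs."""
from __future__ import annotations

from importlib import resources

import yaml

from .features import FeatureConfig
from .inversion import FitBounds

__all__ = ["load_config", "bounds_from_config", "feature_config_from_config"]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None = None) -> dict:
    """Packaged defaults, optionally merged with a user YAML file."""
    ref = resources.files("spectromics.data").joinpath("default_config.yaml")
    cfg = yaml.safe_load(ref.read_text())
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def bounds_from_config(cfg: dict) -> FitBounds:
    spec = cfg["fit_bounds"]
    return FitBounds({k: float(v[0]) for k, v in spec.items()},
                     {k: float(v[1]) for k, v in spec.items()},
                     {k: float(v[2]) for k, v in spec.items()})


def feature_config_from_config(cfg: dict) -> FeatureConfig:
    f = cfg["features"]
    return FeatureConfig(ng=int(f["ng"]), delta=int(f["delta"]),
                         angles=tuple(f["angles"]))
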