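"""Run configuration: YAML round-trip of priors, LUT settings, noise and
paths.  Every prior default is overridable here rather than hard-coded in
the operations."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .priors import ParameterPrior, default_priors
from .rtm import Geometry
from .scene import NoiseModel


@dataclass
class RunConfig:
    priors: dict = field(default_factory=default_priors)
    lut_size: int = 100_000
    seed: int = 0
    fraction: float = 0.10
    strategy: str = "B1+B2+B3+B4"
    noise: NoiseModel = field(default_factory=NoiseModel)
    geometry: Geometry = field(default_factory=lambda: Geometry(46.0, 32.0, 90.0, 0.1))
    eps_observed: float = 1e-6
    constants_csv: str | None = None
    soil_csv: str | None = None
    srf_csv: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ConfigError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.lut_size < 1:
            raise ConfigError(f"lut_size must be >= 1, got {self.lut_size}")


def _prior_to_dict(p: ParameterPrior) -> dict:
    return {"name": p.name, "unit": p.unit, "dist": p.dist,
            "min": p.minimum, "max": p.maximum, "mode": p.mode, "std": p.std}


def _prior_from_dict(d: dict) -> ParameterPrior:
    return ParameterPrior(name=d["name"], unit=d.get("unit", "-"),
                          dist=d["dist"], minimum=d.get("min"),
                          maximum=d.get("max"), mode=d.get("mode"),
                          std=d.get("std"))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    doc = {
        "lut_size": cfg.lut_size, "seed": cfg.seed, "fraction": cfg.fraction,
        "strategy": cfg.strategy, "eps_observed": cfg.eps_observed,
        "geometry": {"tts": cfg.geometry.tts, "tto": cfg.geometry.tto,
                     "psi": cfg.geometry.psi, "skyl": cfg.geometry.skyl},
        "noise": {"band_relative_sigma": cfg.noise.band_relative_sigma,
                  "band_additive_sigma": cfg.noise.band_additive_sigma,
                  "lai_sigma": cfg.noise.lai_sigma,
                  "spad_sigma": cfg.noise.spad_sigma},
        "priors": [_prior_to_dict(p) for p in cfg.priors.values()],
        "paths": {"constants_csv": cfg.constants_csv, "soil_csv": cfg.soil_csv,
                  "srf_csv": cfg.srf_csv},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    priors = default_priors()
    for entry in doc.get("priors", []):
        p = _prior_from_dict(entry)
        priors[p.name] = p
    geo = doc.get("geometry", {})
    noi = doc.get("noise", {})
    paths = doc.get("paths", {})
    return RunConfig(
        priors=priors,
        lut_size=int(doc.get("lut_size", 100_000)),
        seed=int(doc.get("seed", 0)),
        fraction=float(doc.get("fraction", 0.10)),
        strategy=str(doc.get("strategy", "B1+B2+B3+B4")),
        noise=NoiseModel(
            band_relative_sigma=float(noi.get("band_relative_sigma", 0.03)),
            band_additive_sigma=float(noi.get("band_additive_sigma", 0.005)),
            lai_sigma=float(noi.get("lai_sigma", 0.3)),
            spad_sigma=float(noi.get("spad_sigma", 1.5)),
        ),
        geometry=Geometry(tts=float(geo.get("tts", 46.0)),
                          tto=float(geo.get("tto", 32.0)),
                          psi=float(geo.get("psi", 90.0)),
                          skyl=float(geo.get("skyl", 0.1))),
        eps_observed=float(doc.get("eps_observed", 1e-6)),
        constants_csv=paths.get("constants_csv"),
        soil_csv=paths.get("soil_csv"),
        srf_csv=paths.get("srf_csv"),
    )


def parse_strategy(label: str):
    """Parse a strategy label: 'B2', 'B2+B4', or a VI name like 'GNDVI'."""
    from .indices import VI_NAMES
    from .lut import Strategy

    label = label.strip()
    if label.upper() in VI_NAMES:
        return Strategy(kind="vi", vi=label.upper())
    parts = tuple(p.strip().upper() for p in label.replace(",", "+").split("+") if p.strip())
    return Strategy(kind="bands", bands=parts)
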