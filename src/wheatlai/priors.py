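"""Prior distributions of the PROSAIL variables and the SPAD-to-Cab
field-calibration transfer.

The retrieval treats nine variables as free — leaf structure Ni,
chlorophyll Cab, water Cw, dry matter Cm, brown pigment Cbp, canopy LAI,
mean leaf inclination ALIA, hot-spot hspot, soil brightness psoil — and
fixes the geometry (skyl, tts, tto, psi) per scene.  Gaussian priors are
truncated to their [min, max] range by rejection sampling.

The "physical_cw" preset replaces the anomalously large equivalent water
thickness range (0.60-0.85 cm) with a physiologically typical one
(0.006-0.035 cm); the default keeps the large range, which is what the
retrieval study design prescribes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ParameterDomainError

FREE_NAMES = ("ni", "cab", "cw", "cm", "cbp", "lai", "alia", "hspot", "psoil")
FIXED_NAMES = ("skyl", "tts", "tto", "psi")
ALL_NAMES = FREE_NAMES + FIXED_NAMES


@dataclass(frozen=True)
class ParameterPrior:
    """One variable's prior: truncated-gaussian (mode, std on [min, max]),
    uniform on [min, max], or fixed at ``mode``."""

    name: str
    unit: str
    dist: str  # "truncated-gaussian" | "uniform" | "fixed"
    minimum: float | None = None
    maximum: float | None = None
    mode: float | None = None
    std: float | None = None

    def __post_init__(self) -> None:
        if self.dist not in ("truncated-gaussian", "uniform", "fixed"):
            raise ConfigError(f"unknown distribution {self.dist!r} for {self.name}")
        if self.dist == "fixed":
            if self.mode is None:
                raise ConfigError(f"fixed prior {self.name} needs a value (mode)")
            return
        if self.minimum is None or self.maximum is None:
            raise ConfigError(f"prior {self.name} needs min and max")
        if self.minimum > self.maximum:
            raise ConfigError(f"prior {self.name}: min {self.minimum} > max {self.maximum}")
        if self.dist == "truncated-gaussian":
            if self.std is None or self.std <= 0:
                raise ConfigError(f"prior {self.name}: gaussian needs std > 0")
            if self.mode is None or not self.minimum <= self.mode <= self.maximum:
                raise ConfigError(f"prior {self.name}: mode must lie in [min, max]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "fixed":
            return np.full(n, float(self.mode))
        if self.dist == "uniform":
            return rng.uniform(self.minimum, self.maximum, n)
        # truncated gaussian by rejection: redraw out-of-range values
        out = rng.normal(self.mode, self.std, n)
        bad = (out < self.minimum) | (out > self.maximum)
        while bad.any():
            out[bad] = rng.normal(self.mode, self.std, int(bad.sum()))
            bad = (out < self.minimum) | (out > self.maximum)
        return out


def default_priors(cw_preset: str = "as-printed") -> dict[str, ParameterPrior]:
    """The thirteen study priors (nine free variables, four fixed geometry
    values).  ``cw_preset``: "as-printed" (0.60-0.85 cm) or "physical_cw"."""
    if cw_preset == "as-printed":
        cw = ParameterPrior("cw", "cm", "uniform", 0.60, 0.85)
    elif cw_preset == "physical_cw":
        cw = ParameterPrior("cw", "cm", "uniform", 0.006, 0.035)
    else:
        raise ConfigError(f"unknown cw preset {cw_preset!r}")
    g = "truncated-gaussian"
    priors = [
        ParameterPrior("ni", "-", g, 1.2, 1.8, 1.5, 0.3),
        ParameterPrior("cab", "ug cm-2", g, 25.0, 75.0, 50.0, 7.5),
        cw,
        ParameterPrior("cm", "g cm-2", g, 0.003, 0.011, 0.007, 0.002),
        ParameterPrior("cbp", "ug cm-2", g, 0.0, 0.2, 0.0, 0.3),
        ParameterPrior("lai", "-", "uniform", 0.0, 8.0),
        ParameterPrior("alia", "deg", g, 30.0, 80.0, 60.0, 4.0),
        ParameterPrior("hspot", "-", g, 0.1, 0.5, 0.3, 0.2),
        ParameterPrior("psoil", "-", g, 0.5, 3.5, 1.2, 2.0),
        ParameterPrior("skyl", "fraction", "fixed", mode=0.1),
        ParameterPrior("tts", "deg", "fixed", minimum=25.0, maximum=70.0, mode=46.0),
        ParameterPrior("tto", "deg", "fixed", minimum=0.0, maximum=80.0, mode=32.0),
        ParameterPrior("psi", "deg", "fixed", minimum=-120.0, maximum=120.0, mode=90.0),
    ]
    return {p.name: p for p in priors}


def sample_parameters(priors: dict[str, ParameterPrior], n: int,
                      seed: int | np.random.Generator) -> "pd.DataFrame":
    """Draw ``n`` parameter sets; identical seed gives identical output.

    Returns a DataFrame with one column per variable in ALL_NAMES order
    (missing fixed variables are allowed only if absent from ``priors``).
    """
    import pandas as pd

    if n < 1:
        raise ConfigError(f"sample count must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {}
    for name in ALL_NAMES:
        if name in priors:
            cols[name] = priors[name].sample(rng, n)
    return pd.DataFrame(cols)


# SPAD-to-Cab transfer calibrated on destructive leaf samples:
# Cab = 5.6351 * exp(0.0287 * SPAD + 0.8095)
_A = 5.6351
_B = 0.0287
_C = 0.8095


def spad_to_cab(spad):
    """Chlorophyll a+b (ug cm-2) from a SPAD chlorophyll-meter reading."""
    spad_arr = np.asarray(spad, dtype=float)
    if np.any(spad_arr < 0):
        raise ParameterDomainError("SPAD reading must be >= 0")
    out = _A * np.exp(spad_arr * _B + _C)
    return float(out) if np.isscalar(spad) or out.ndim == 0 else out


def cab_to_spad(cab):
    """Analytic inverse of :func:`spad_to_cab`."""
    cab_arr = np.asarray(cab, dtype=float)
    if np.any(cab_arr <= _A * math.exp(_C) * 1e-12):
        raise ParameterDomainError("Cab must be positive")
    out = (np.log(cab_arr / _A) - _C) / _B
    return float(out) if np.isscalar(cab) or out.ndim == 0 else out
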