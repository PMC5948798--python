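"""Synthetic wheat scenes with the statistical structure the retrieval
assumes: per-pixel biophysical truth fields with mild spatial
autocorrelation, forward-simulated 4-band reflectance, band noise, and
validation plots emulating a field campaign (44 homogeneous plots with
instrument noise on LAI and SPAD readings).

Two stage profiles are provided.  "elongation" concentrates LAI around
3.5 with a tail of thin late-sown pixels and no brown pigment;
"grain_filling" concentrates LAI between 3 and 6 with elevated brown
pigment from senescing leaves.  Both default to the common retrieval
geometry (tts=46, tto=32, psi=90, skyl=0.1) so a single LUT serves scene
and plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .errors import ConfigError
from .lut import simulate_bands
from .optics import OpticalConstants, load_optical_constants
from .priors import FREE_NAMES, ParameterPrior, cab_to_spad, default_priors
from .rtm import Geometry
from .sensor import SpectralResponse, load_srf

STAGE_NAMES = ("elongation", "grain_filling")


@dataclass(frozen=True)
class NoiseModel:
    """Observation/measurement noise settings.

    band_relative_sigma: multiplicative reflectance noise per band;
    band_additive_sigma: additive reflectance noise; lai_sigma: plot LAI
    measurement noise (LAI units); spad_sigma: SPAD reading noise.
    """

    band_relative_sigma: float = 0.03
    band_additive_sigma: float = 0.005
    lai_sigma: float = 0.3
    spad_sigma: float = 1.5

    def __post_init__(self) -> None:
        for name in ("band_relative_sigma", "band_additive_sigma",
                     "lai_sigma", "spad_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"noise sigma {name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)


def _stage_distributions(stage: str) -> dict[str, ParameterPrior]:
    """Generating distributions of the truth fields for one stage."""
    base = {k: v for k, v in default_priors().items() if k in FREE_NAMES}
    g = "truncated-gaussian"
    if stage == "elongation":
        base["lai"] = ParameterPrior("lai", "-", g, 0.5, 5.0, 3.5, 1.0)
        base["cbp"] = ParameterPrior("cbp", "ug cm-2", "fixed", mode=0.0)
    elif stage == "grain_filling":
        base["lai"] = ParameterPrior("lai", "-", g, 3.0, 6.0, 4.5, 1.0)
        base["cbp"] = ParameterPrior("cbp", "ug cm-2", "uniform", 0.05, 0.2)
    else:
        raise ConfigError(f"unknown stage {stage!r}; expected one of {STAGE_NAMES}")
    return base


@dataclass(frozen=True)
class StageProfile:
    """Scene-generating profile: stage name, per-parameter truth
    distributions and the scene geometry."""

    stage: str
    distributions: dict = None
    geometry: Geometry = Geometry(tts=46.0, tto=32.0, psi=90.0, skyl=0.1)
    allow_out_of_prior: bool = False

    def __post_init__(self) -> None:
        if self.distributions is None:
            object.__setattr__(self, "distributions", _stage_distributions(self.stage))
        if not self.allow_out_of_prior:
            priors = default_priors()
            for name, dist in self.distributions.items():
                p = priors[name]
                if p.dist == "fixed" or dist.dist == "fixed":
                    continue
                if dist.minimum < p.minimum - 1e-9 or dist.maximum > p.maximum + 1e-9:
                    raise ConfigError(
                        f"{self.stage}: generating range for {name} "
                        f"[{dist.minimum}, {dist.maximum}] exceeds the prior support "
                        f"[{p.minimum}, {p.maximum}] (set allow_out_of_prior to force)")


@dataclass
class TrueScene:
    """A generated scene: truth rasters per free parameter, the observed
    4-band reflectance raster, and the settings that produced them."""

    stage: str
    truth: dict
    observed: np.ndarray          # (rows, cols, 4)
    geometry: Geometry
    noise: NoiseModel
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.observed.shape[:2]


def _quantile_field(dist: ParameterPrior, u: np.ndarray) -> np.ndarray:
    if dist.dist == "fixed":
        return np.full_like(u, float(dist.mode))
    if dist.dist == "uniform":
        return dist.minimum + u * (dist.maximum - dist.minimum)
    a = (dist.minimum - dist.mode) / dist.std
    b = (dist.maximum - dist.mode) / dist.std
    return stats.truncnorm.ppf(u, a, b, loc=dist.mode, scale=dist.std)


def generate_scene(
    profile: StageProfile,
    rows: int = 200,
    cols: int = 200,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    smooth_sigma: float = 3.0,
    constants: OpticalConstants | None = None,
    srf: SpectralResponse | None = None,
) -> TrueScene:
    """Generate a synthetic scene.

    Truth fields are Gaussian random fields smoothed with a kernel of
    ``smooth_sigma`` pixels, then mapped through each parameter's
    generating distribution by probability-integral transform, so marginals
    are exact and fields are spatially correlated.  The observed raster is
    the forward simulation perturbed by multiplicative and additive band
    noise, clipped to [0, 1].
    """
    if rows < 1 or cols < 1:
        raise ConfigError("scene must have at least one pixel")
    constants = constants or load_optical_constants()
    srf = srf or load_srf()
    rng = np.random.default_rng(seed)

    truth = {}
    for name in FREE_NAMES:
        white = rng.standard_normal((rows, cols))
        smooth = ndimage.gaussian_filter(white, smooth_sigma, mode="reflect")
        sd = smooth.std()
        z = smooth / sd if sd > 0 else np.zeros_like(smooth)
        u = np.clip(stats.norm.cdf(z), 1e-9, 1.0 - 1e-9)
        truth[name] = _quantile_field(profile.distributions[name], u)

    import pandas as pd

    flat = pd.DataFrame({name: truth[name].ravel() for name in FREE_NAMES})
    g = profile.geometry
    flat["skyl"], flat["tts"], flat["tto"], flat["psi"] = g.skyl, g.tts, g.tto, g.psi
    sim = simulate_bands(flat, constants, srf, g).reshape(rows, cols, 4)

    observed = sim.copy()
    if noise.band_relative_sigma > 0:
        observed = observed * (1.0 + noise.band_relative_sigma
                               * rng.standard_normal(observed.shape))
    if noise.band_additive_sigma > 0:
        observed = observed + noise.band_additive_sigma * rng.standard_normal(observed.shape)
    observed = np.clip(observed, 0.0, 1.0)

    return TrueScene(stage=profile.stage, truth=truth, observed=observed,
                     geometry=g, noise=noise, seed=seed)


def generate_plots(
    scene: TrueScene,
    n_plots: int = 44,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    min_spacing_px: float = 6.0,
):
    """Place validation plots at mutually distant pixels and record noisy
    LAI and SPAD measurements.

    Measured LAI is the true pixel LAI plus Gaussian noise truncated at 0;
    SPAD is the analytic inverse of the chlorophyll transfer applied to the
    true pixel Cab, plus reading noise; observed bands are copied from the
    scene raster.
    """
    from .strategies import PlotRecord

    rows, cols = scene.shape
    if n_plots > rows * cols:
        raise ConfigError(f"{n_plots} plots do not fit a {rows}x{cols} scene")
    rng = np.random.default_rng(seed)

    placed: list[tuple[int, int]] = []
    tries = 0
    max_tries = 500 * n_plots
    while len(placed) < n_plots:
        if tries >= max_tries:
            raise ConfigError(
                f"could not place {n_plots} plots with spacing "
                f">= {min_spacing_px} px in a {rows}x{cols} scene; "
                "reduce n_plots or enlarge the scene")
        r = int(rng.integers(0, rows))
        c = int(rng.integers(0, cols))
        tries += 1
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_spacing_px ** 2
               for pr, pc in placed):
            placed.append((r, c))

    plots = []
    for i, (r, c) in enumerate(placed):
        lai_true = float(scene.truth["lai"][r, c])
        lai_meas = max(0.0, lai_true + (rng.normal(0.0, noise.lai_sigma)
                                        if noise.lai_sigma > 0 else 0.0))
        spad_true = cab_to_spad(float(scene.truth["cab"][r, c]))
        spad = max(0.0, spad_true + (rng.normal(0.0, noise.spad_sigma)
                                     if noise.spad_sigma > 0 else 0.0))
        plots.append(PlotRecord(
            plot_id=f"P{i + 1:03d}", x=float(c), y=float(r),
            lai_measured=lai_meas, bands=scene.observed[r, c].copy(), spad=spad,
        ))
    return plots


def stage_profile(stage: str, geometry: Geometry | None = None) -> StageProfile:
    """Convenience constructor for a named stage profile."""
    prof = StageProfile(stage=stage)
    if geometry is not None:
        prof = replace(prof, geometry=geometry)
    return prof
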