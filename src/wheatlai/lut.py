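"""Look-up-table construction and inversion.

A LUT holds N parameter sets drawn from the priors together with their
forward-simulated broadband signatures and vegetation indices.  Inversion
of an observation under a *strategy* (a non-empty subset of the four bands,
or one vegetation index) ranks entries by the relative root-mean-square
error cost

    bands: RRMSE = sqrt( (1/m) * sum_i ((R_obs,i - R_sim,i) / R_obs,i)^2 )
    VI:    RRMSE = |VI_obs - VI_sim| / |VI_obs|

and averages the parameter vectors of the smallest ceil(fraction * N)
entries (fraction defaults to the study's 10% multiple-solution rule).
Ties at the cut boundary are broken by entry insertion index (stable sort),
so inversion is deterministic and invariant to relabeling of equal costs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import indices
from .errors import ConfigError, DataError, InversionFailedError, UndefinedCostError
from .optics import OpticalConstants, load_optical_constants
from .priors import ALL_NAMES, FREE_NAMES, ParameterPrior, sample_parameters
from .rtm import Geometry, prospect_batch, sail_batch
from .sensor import BAND_IDS, SpectralResponse, band_convolve_batch

#: guard below which an observed reflectance or index is treated as undefined
EPS_OBSERVED = 1e-6

_BAND_INDEX = {b: i for i, b in enumerate(BAND_IDS)}


@dataclass(frozen=True)
class Strategy:
    """A retrieval strategy: kind "bands" with a non-empty band subset, or
    kind "vi" with one vegetation index name."""

    kind: str
    bands: tuple[str, ...] = ()
    vi: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "bands":
            if not self.bands or any(b not in BAND_IDS for b in self.bands):
                raise ConfigError(f"invalid band subset {self.bands}")
            if len(set(self.bands)) != len(self.bands):
                raise ConfigError(f"duplicate bands in {self.bands}")
        elif self.kind == "vi":
            if self.vi not in indices.VI_NAMES:
                raise ConfigError(f"unknown VI {self.vi!r}")
        else:
            raise ConfigError(f"strategy kind must be 'bands' or 'vi', got {self.kind!r}")

    @property
    def label(self) -> str:
        return "+".join(self.bands) if self.kind == "bands" else str(self.vi)


@dataclass
class LUT:
    """Forward-simulated table: parameters (N, 13), band signatures (N, 4)
    and vegetation indices (N, 10), plus provenance metadata."""

    params: pd.DataFrame
    bands: np.ndarray
    vis: np.ndarray
    geometry: Geometry
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.params)

    def to_frame(self) -> pd.DataFrame:
        """One row per entry: 13 parameters, 4 bands, 10 VIs."""
        out = self.params.copy()
        for i, b in enumerate(BAND_IDS):
            out[b] = self.bands[:, i]
        for i, v in enumerate(indices.VI_NAMES):
            out[v] = self.vis[:, i]
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            params=self.params.to_numpy(),
            param_names=np.array(list(self.params.columns)),
            bands=self.bands,
            vis=self.vis,
            geometry=np.array([self.geometry.tts, self.geometry.tto,
                               self.geometry.psi, self.geometry.skyl]),
            meta=np.array([json.dumps(self.meta)]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LUT":
        with np.load(path, allow_pickle=False) as z:
            params = pd.DataFrame(z["params"], columns=list(z["param_names"]))
            g = z["geometry"]
            return cls(params=params, bands=z["bands"], vis=z["vis"],
                       geometry=Geometry(tts=float(g[0]), tto=float(g[1]),
                                         psi=float(g[2]), skyl=float(g[3])),
                       meta=json.loads(str(z["meta"][0])))

    def export_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class InversionResult:
    lai: float
    posterior_means: dict
    n_averaged: int
    min_cost: float


def simulate_bands(params: pd.DataFrame, constants: OpticalConstants,
                   srf: SpectralResponse, geometry: Geometry,
                   chunk: int = 2000) -> np.ndarray:
    """Forward-simulate broadband signatures for a table of parameter sets.

    Runs PROSPECT-5 + 4SAIL on the wavelength slice covering the SRF
    support only, then convolves to the four bands.  Returns (N, 4).
    """
    support = srf.wl[srf.weights.sum(axis=1) > 0]
    c = constants.slice(support.min(), support.max())
    wmat = srf.normalized_matrix(c.wl)

    n = len(params)
    leaf_cols = params[["ni", "cab", "cw", "cm", "cbp"]].to_numpy()
    lai = params["lai"].to_numpy()
    alia = params["alia"].to_numpy()
    hspot = params["hspot"].to_numpy()
    psoil = params["psoil"].to_numpy()

    out = np.empty((n, 4))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        rho, tau = prospect_batch(leaf_cols[lo:hi], c)
        rsoil = np.clip(psoil[lo:hi, None] * c.soil_dry[None, :], 0.0, 1.0)
        rso, rdo = sail_batch(rho, tau, rsoil, lai[lo:hi], alia[lo:hi],
                              hspot[lo:hi], geometry)
        refl = (1.0 - geometry.skyl) * rso + geometry.skyl * rdo
        out[lo:hi] = np.clip(refl, 0.0, 1.0) @ wmat
    return np.clip(out, 0.0, 1.0)


def _config_hash(priors, geometry, srf, n, seed) -> str:
    h = hashlib.sha256()
    for name in sorted(priors):
        p = priors[name]
        h.update(repr((p.name, p.unit, p.dist, p.minimum, p.maximum,
                       p.mode, p.std)).encode())
    h.update(repr((geometry.tts, geometry.tto, geometry.psi, geometry.skyl)).encode())
    h.update(srf.wl.tobytes())
    h.update(srf.weights.tobytes())
    h.update(repr((n, seed)).encode())
    return h.hexdigest()[:16]


def build_lut(
    priors: dict[str, ParameterPrior],
    geometry: Geometry,
    srf: SpectralResponse,
    n: int = 100_000,
    seed: int = 0,
    constants: OpticalConstants | None = None,
    cache_dir: str | Path | None = None,
) -> LUT:
    """Build (or load from cache) an N-entry LUT for one scene geometry."""
    key = None
    if cache_dir is not None:
        key = _config_hash(priors, geometry, srf, n, seed)
        cache_path = Path(cache_dir) / f"lut_{key}.npz"
        if cache_path.exists():
            return LUT.load(cache_path)

    constants = constants or load_optical_constants()
    params = sample_parameters(priors, n, seed)
    # scene geometry overrides any fixed-prior defaults in the stored table
    params["skyl"] = geometry.skyl
    params["tts"] = geometry.tts
    params["tto"] = geometry.tto
    params["psi"] = geometry.psi
    params = params[list(ALL_NAMES)]

    bands = simulate_bands(params, constants, srf, geometry)
    vis = indices.compute_vi_matrix(bands)
    lut = LUT(params=params, bands=bands, vis=vis, geometry=geometry,
              meta={"n": n, "seed": seed, "config_hash": key or ""})
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        lut.save(Path(cache_dir) / f"lut_{key}.npz")
    return lut


# ---------------------------------------------------------------------------
# cost functions


def rrmse_bands(observed, simulated, subset: tuple[str, ...] = BAND_IDS) -> float:
    """Relative RMSE between observed and simulated reflectance over a band
    subset; the relative error is taken against the observed value."""
    obs = observed.as_array() if hasattr(observed, "as_array") else np.asarray(observed, float)
    sim = simulated.as_array() if hasattr(simulated, "as_array") else np.asarray(simulated, float)
    idx = [_BAND_INDEX[b] for b in subset]
    o, s = obs[idx], sim[idx]
    if np.any(np.abs(o) < EPS_OBSERVED):
        raise UndefinedCostError(f"observed reflectance below {EPS_OBSERVED} in {subset}")
    return float(np.sqrt(np.mean(((o - s) / o) ** 2)))


def rrmse_vi(observed_vi: float, simulated_vi: float) -> float:
    """Single-index relative error cost |obs - sim| / |obs|."""
    if abs(observed_vi) < EPS_OBSERVED:
        raise UndefinedCostError(f"observed VI magnitude below {EPS_OBSERVED}")
    return float(abs(observed_vi - simulated_vi) / abs(observed_vi))


# ---------------------------------------------------------------------------
# inversion


def _cost_matrix(observations: np.ndarray, strategy: Strategy, lut: LUT) -> np.ndarray:
    """Costs (P, N) for P observed band signatures; NaN where undefined."""
    obs = np.atleast_2d(np.asarray(observations, float))
    if strategy.kind == "bands":
        idx = [_BAND_INDEX[b] for b in strategy.bands]
        o = obs[:, idx]                                   # (P, m)
        s = lut.bands[:, idx]                             # (N, m)
        bad = np.any(np.abs(o) < EPS_OBSERVED, axis=1)    # (P,)
        o_safe = np.where(np.abs(o) < EPS_OBSERVED, 1.0, o)
        rel = (o_safe[:, None, :] - s[None, :, :]) / o_safe[:, None, :]
        cost = np.sqrt(np.mean(rel ** 2, axis=2))
        cost[bad] = np.nan
        return cost
    vi_idx = indices.VI_NAMES.index(strategy.vi)
    o = indices.compute_vi(strategy.vi, obs)              # (P,)
    s = lut.vis[:, vi_idx]                                # (N,)
    bad = ~np.isfinite(o) | (np.abs(o) < EPS_OBSERVED)
    o_safe = np.where(bad, 1.0, o)
    cost = np.abs(o_safe[:, None] - s[None, :]) / np.abs(o_safe[:, None])
    cost[bad] = np.nan
    cost[:, ~np.isfinite(s)] = np.inf
    return cost


def invert_batch(observations: np.ndarray, strategy: Strategy, lut: LUT,
                 fraction: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Invert P observations at once.

    Returns (posterior_mean_params (P, n_free), min_cost (P,)); rows are
    NaN where the observation admits no defined cost.  Parameter columns
    follow FREE_NAMES order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigError(f"solution fraction must be in (0, 1], got {fraction}")
    if len(lut) == 0:
        raise DataError("empty LUT")
    n_sel = math.ceil(fraction * len(lut))
    free = lut.params[list(FREE_NAMES)].to_numpy()
    obs = np.atleast_2d(np.asarray(observations, float))
    P = obs.shape[0]
    means = np.full((P, len(FREE_NAMES)), np.nan)
    min_cost = np.full(P, np.nan)
    # chunk observations so the (P, N) cost matrix stays small in memory
    block = max(1, int(2e7 // max(len(lut), 1)))
    for lo in range(0, P, block):
        cost_blk = _cost_matrix(obs[lo:lo + block], strategy, lut)
        for pb in range(cost_blk.shape[0]):
            p = lo + pb
            c = cost_blk[pb]
            if not np.any(np.isfinite(c)):
                continue
            # stable sort on (cost, insertion index); NaN/inf sort last
            order = np.argsort(c, kind="stable")[:n_sel]
            sel_cost = c[order]
            if not np.all(np.isfinite(sel_cost)):
                finite = np.isfinite(sel_cost)
                order = order[finite]
                sel_cost = sel_cost[finite]
                if order.size == 0:
                    continue
            means[p] = free[order].mean(axis=0)
            min_cost[p] = sel_cost[0]
    return means, min_cost


def invert(observation, strategy: Strategy, lut: LUT,
           fraction: float = 0.10) -> InversionResult:
    """Invert one observed band signature under a strategy.

    The LAI estimate is the arithmetic mean over the selected entries; the
    posterior means of all nine free parameters are also reported.
    """
    obs = observation.as_array() if hasattr(observation, "as_array") \
        else np.asarray(observation, float)
    means, min_cost = invert_batch(obs[None, :], strategy, lut, fraction)
    if not np.all(np.isfinite(means[0])):
        raise InversionFailedError(
            f"no LUT entry yields a defined {strategy.label} cost for this observation")
    post = {name: float(v) for name, v in zip(FREE_NAMES, means[0])}
    n_sel = min(math.ceil(fraction * len(lut)), len(lut))
    return InversionResult(lai=post["lai"], posterior_means=post,
                           n_averaged=n_sel, min_cost=float(min_cost[0]))
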