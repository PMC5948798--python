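"""Leaf optical constants and reference soil spectra.

The canonical working grid is 400-2500 nm at 1 nm spacing (2101 samples).
Constants are loaded from CSV fixtures (vendored synthetic tables by
default, real tables droppable by path) and linearly resampled onto the
working grid at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

WL_MIN = 400.0
WL_MAX = 2500.0
WL_STEP = 1.0
N_WL = 2101

#: default carotenoid content (ug cm-2); a PROSPECT-5 input the retrieval
#: priors do not vary, held at a typical green-leaf value.
DEFAULT_CAR = 8.0


def working_grid() -> np.ndarray:
    """The 400-2500 nm, 1 nm wavelength grid (2101 samples)."""
    return WL_MIN + WL_STEP * np.arange(N_WL)


@dataclass(frozen=True)
class OpticalConstants:
    """Wavelength-indexed constants of the leaf and soil forward model.

    Attributes
    ----------
    wl : ndarray
        Wavelength grid in nm, strictly increasing, uniform spacing.
    n : ndarray
        Leaf refractive index (unitless).
    k_cab, k_car, k_brown : ndarray
        Specific absorption coefficients per ug cm-2 of chlorophyll a+b,
        carotenoids and brown pigment.
    k_w : ndarray
        Water absorption per cm of equivalent water thickness.
    k_m : ndarray
        Dry-matter absorption per g cm-2.
    soil_dry, soil_wet : ndarray
        Reference soil reflectance spectra in [0, 1].
    """

    wl: np.ndarray
    n: np.ndarray
    k_cab: np.ndarray
    k_car: np.ndarray
    k_brown: np.ndarray
    k_w: np.ndarray
    k_m: np.ndarray
    soil_dry: np.ndarray
    soil_wet: np.ndarray

    def __post_init__(self) -> None:
        arrays = (self.n, self.k_cab, self.k_car, self.k_brown,
                  self.k_w, self.k_m, self.soil_dry, self.soil_wet)
        if any(a.shape != self.wl.shape for a in arrays):
            raise DataError("optical-constant arrays differ in length from the grid")
        dw = np.diff(self.wl)
        if self.wl.size < 2 or np.any(dw <= 0) or not np.allclose(dw, dw[0]):
            raise DataError("wavelength grid must be strictly increasing and uniform")
        for name in ("k_cab", "k_car", "k_brown", "k_w", "k_m"):
            if np.any(getattr(self, name) < 0):
                raise DataError(f"absorption coefficient {name} has negative values")
        for name in ("soil_dry", "soil_wet"):
            s = getattr(self, name)
            if np.any((s < 0) | (s > 1)):
                raise DataError(f"soil spectrum {name} outside [0, 1]")

    @property
    def n_wl(self) -> int:
        return int(self.wl.size)

    def slice(self, wl_min: float, wl_max: float) -> "OpticalConstants":
        """Restrict to wl_min <= wl <= wl_max (used to speed up LUT builds
        when only the sensor band supports are needed)."""
        m = (self.wl >= wl_min) & (self.wl <= wl_max)
        if not m.any():
            raise DataError("empty wavelength slice")
        return replace(
            self,
            wl=self.wl[m], n=self.n[m], k_cab=self.k_cab[m], k_car=self.k_car[m],
            k_brown=self.k_brown[m], k_w=self.k_w[m], k_m=self.k_m[m],
            soil_dry=self.soil_dry[m], soil_wet=self.soil_wet[m],
        )


def _resample(wl_src: np.ndarray, y: np.ndarray, wl_dst: np.ndarray) -> np.ndarray:
    if wl_src[0] > wl_dst[0] + 1e-9 or wl_src[-1] < wl_dst[-1] - 1e-9:
        raise DataError(
            f"table covers {wl_src[0]:.0f}-{wl_src[-1]:.0f} nm, "
            f"grid needs {wl_dst[0]:.0f}-{wl_dst[-1]:.0f} nm"
        )
    return np.interp(wl_dst, wl_src, y)


def _default_path(name: str) -> Path:
    return Path(str(resources.files("wheatlai").joinpath("data", name)))


def load_optical_constants(
    constants_csv: str | Path | None = None,
    soil_csv: str | Path | None = None,
) -> OpticalConstants:
    """Load (and resample to the working grid) optical constants and soils.

    ``constants_csv`` needs columns wavelength_nm, n, k_cab, k_car, k_brown,
    k_w, k_m; ``soil_csv`` needs wavelength_nm, dry, wet.  Defaults are the
    vendored synthetic tables.
    """
    constants_csv = constants_csv or _default_path("optical_constants_synthetic.csv")
    soil_csv = soil_csv or _default_path("soil_spectra_synthetic.csv")
    wl = working_grid()

    tab = pd.read_csv(constants_csv)
    need = {"wavelength_nm", "n", "k_cab", "k_car", "k_brown", "k_w", "k_m"}
    if not need.issubset(tab.columns):
        raise DataError(f"constants CSV missing columns {sorted(need - set(tab.columns))}")
    tab = tab.sort_values("wavelength_nm")
    src = tab["wavelength_nm"].to_numpy(dtype=float)

    soil = pd.read_csv(soil_csv)
    if not {"wavelength_nm", "dry", "wet"}.issubset(soil.columns):
        raise DataError("soil CSV must have columns wavelength_nm, dry, wet")
    soil = soil.sort_values("wavelength_nm")
    soil_src = soil["wavelength_nm"].to_numpy(dtype=float)

    def col(frame, grid, name):
        return _resample(grid, frame[name].to_numpy(dtype=float), wl)

    return OpticalConstants(
        wl=wl,
        n=col(tab, src, "n"),
        k_cab=col(tab, src, "k_cab"),
        k_car=col(tab, src, "k_car"),
        k_brown=col(tab, src, "k_brown"),
        k_w=col(tab, src, "k_w"),
        k_m=col(tab, src, "k_m"),
        soil_dry=col(soil, soil_src, "dry"),
        soil_wet=col(soil, soil_src, "wet"),
    )


def synthetic_constants(wl: np.ndarray | None = None) -> OpticalConstants:
    """Build the synthetic constants directly from the analytic recipes
    (bypassing the CSV fixtures; used by the fixture generator and tests)."""
    from . import synthspec

    wl = working_grid() if wl is None else np.asarray(wl, dtype=float)
    return OpticalConstants(
        wl=wl,
        n=synthspec.refractive_index(wl),
        k_cab=synthspec.k_chlorophyll(wl),
        k_car=synthspec.k_carotenoid(wl),
        k_brown=synthspec.k_brown(wl),
        k_w=synthspec.k_water(wl),
        k_m=synthspec.k_dry_matter(wl),
        soil_dry=synthspec.soil_dry(wl),
        soil_wet=synthspec.soil_wet(wl),
    )
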