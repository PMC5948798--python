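"""GF-1 WFV sensor abstraction: spectral response convolution to the four
broadbands (Blue, Green, Red, NIR) and DN-to-radiance calibration."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

BAND_IDS = ("B1", "B2", "B3", "B4")

#: Radiometric calibration gains (W m-2 sr-1 um-1 per DN) and offsets of the
#: GF-1 WFV camera, per band.
DEFAULT_GAINS = {"B1": 0.1816, "B2": 0.1560, "B3": 0.1412, "B4": 0.1368}
DEFAULT_OFFSETS = {"B1": 0.0, "B2": 0.0, "B3": 0.0, "B4": 0.0}


@dataclass(frozen=True)
class SpectralResponse:
    """Per-band relative spectral response on a common wavelength grid.

    ``weights`` has shape (n_wl, 4) with columns in BAND_IDS order; weights
    need not be normalized (normalization happens in the convolution).
    """

    wl: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or self.weights.shape != (self.wl.size, 4):
            raise DataError("SRF weights must have shape (n_wl, 4)")
        if np.any(self.weights < 0):
            raise DataError("SRF weights must be non-negative")
        sums = self.weights.sum(axis=0)
        if np.any(sums <= 0):
            bad = [BAND_IDS[i] for i in np.flatnonzero(sums <= 0)]
            raise DataError(f"SRF bands with no positive weight: {bad}")
        if self.wl.min() < 400.0 - 1e-9 or self.wl.max() > 2500.0 + 1e-9:
            raise DataError("SRF support must lie within 400-2500 nm")

    def resampled_to(self, wl: np.ndarray) -> "SpectralResponse":
        w = np.stack([np.interp(wl, self.wl, self.weights[:, i], left=0.0, right=0.0)
                      for i in range(4)], axis=1)
        return SpectralResponse(wl=np.asarray(wl, float), weights=w)

    def normalized_matrix(self, wl: np.ndarray) -> np.ndarray:
        """(n_wl, 4) weight matrix on grid ``wl``, columns summing to 1."""
        w = self.resampled_to(wl).weights
        sums = w.sum(axis=0)
        if np.any(sums <= 0):
            bad = [BAND_IDS[i] for i in np.flatnonzero(sums <= 0)]
            raise DataError(f"spectrum grid does not cover SRF support of {bad}")
        return w / sums


@dataclass(frozen=True)
class BandSignature:
    """Surface reflectance in the four broadbands, each in [0, 1]."""

    b1: float
    b2: float
    b3: float
    b4: float

    def __post_init__(self) -> None:
        for name in ("b1", "b2", "b3", "b4"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"band {name} reflectance {v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3, self.b4])


@dataclass(frozen=True)
class CalibrationCoefficients:
    gains: dict
    offsets: dict

    def __post_init__(self) -> None:
        for band in BAND_IDS:
            if self.gains.get(band, 0.0) <= 0:
                raise DataError(f"calibration gain for {band} must be > 0")


DEFAULT_CALIBRATION = CalibrationCoefficients(gains=DEFAULT_GAINS,
                                              offsets=DEFAULT_OFFSETS)


def load_srf(path: str | Path | None = None) -> SpectralResponse:
    """Load an SRF table (columns wavelength_nm, b1..b4); default is the
    vendored synthetic Gaussian-lobe SRF matching the nominal band edges."""
    if path is None:
        path = Path(str(resources.files("wheatlai").joinpath(
            "data", "srf_gf1_wfv_synthetic.csv")))
    tab = pd.read_csv(path)
    need = {"wavelength_nm", "b1", "b2", "b3", "b4"}
    if not need.issubset(tab.columns):
        raise DataError(f"SRF CSV missing columns {sorted(need - set(tab.columns))}")
    tab = tab.sort_values("wavelength_nm")
    wl = tab["wavelength_nm"].to_numpy(dtype=float)
    w = tab[["b1", "b2", "b3", "b4"]].to_numpy(dtype=float)
    return SpectralResponse(wl=wl, weights=w)


def band_convolve_batch(spectra: np.ndarray, wl: np.ndarray,
                        srf: SpectralResponse) -> np.ndarray:
    """Convolve spectra (B, n_wl) on grid ``wl`` to band values (B, 4)."""
    spectra = np.atleast_2d(np.asarray(spectra, float))
    if spectra.shape[1] != wl.size:
        raise DataError("spectrum length does not match its wavelength grid")
    return spectra @ srf.normalized_matrix(wl)


def band_convolve(spectrum, srf: SpectralResponse) -> BandSignature:
    """SRF-weighted mean of a canopy spectrum: one reflectance per band."""
    vals = band_convolve_batch(spectrum.reflectance, spectrum.wl, srf)[0]
    vals = np.clip(vals, 0.0, 1.0)
    return BandSignature(*vals)


def dn_to_radiance(dn: float, cal: CalibrationCoefficients = DEFAULT_CALIBRATION,
                   band: str = "B1") -> float:
    """Apparent radiance from a digital number: gain * DN + offset."""
    if band not in BAND_IDS:
        raise DataError(f"unknown band id {band!r}; expected one of {BAND_IDS}")
    if dn < 0:
        raise DataError(f"DN must be >= 0, got {dn}")
    return cal.gains[band] * dn + cal.offsets.get(band, 0.0)
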