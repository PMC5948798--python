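"""Synthetic spectral libraries for the radiative-transfer forward model.

The PROSPECT/SAIL literature distributes measured leaf optical constants
(refractive index and specific absorption coefficients) and reference soil
spectra as data tables.  Those tables are not redistributable here, so this
module synthesizes physically plausible stand-ins from smooth analytic
recipes: Gaussian absorption features at the canonical pigment and water
band positions, a slowly declining refractive index, and a typical bright
dry-soil continuum with water dips.  Every fixture written from these
recipes carries a ``_synthetic`` filename suffix.

The shapes are designed so that broadband Blue/Green/Red/NIR behaviour of a
wheat canopy is qualitatively right: strong chlorophyll absorption in blue
and red, a green reflectance bump, a high NIR plateau that saturates with
leaf area, and a soil line brighter than vegetation in the visible.  They
are NOT the measured PROSPECT-5 coefficients; quantitative agreement with
spectra simulated from the real tables is not claimed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "refractive_index",
    "k_chlorophyll",
    "k_carotenoid",
    "k_brown",
    "k_water",
    "k_dry_matter",
    "soil_dry",
    "soil_wet",
    "gaussian_srf",
]


def _g(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height Gaussian lobe in wavelength."""
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def refractive_index(wl: np.ndarray) -> np.ndarray:
    """Leaf interior refractive index, ~1.52 in the blue declining to ~1.40."""
    wl = np.asarray(wl, dtype=float)
    return 1.40 + 0.12 * np.exp(-(wl - 400.0) / 600.0)


def k_chlorophyll(wl: np.ndarray) -> np.ndarray:
    """Specific absorption of chlorophyll a+b (per ug cm-2).

    Soret-band feature near 430 nm, red feature near 662 nm, and a weak
    broad shoulder so absorption at 550 nm is small but nonzero.
    """
    wl = np.asarray(wl, dtype=float)
    k = (
        0.045 * _g(wl, 430.0, 28.0)
        + 0.032 * _g(wl, 662.0, 22.0)
        + 0.006 * _g(wl, 520.0, 60.0)
    )
    return np.where(wl > 780.0, 0.0, k)


def k_carotenoid(wl: np.ndarray) -> np.ndarray:
    """Specific absorption of carotenoids (per ug cm-2), blue-only."""
    wl = np.asarray(wl, dtype=float)
    k = 0.055 * _g(wl, 450.0, 32.0) + 0.035 * _g(wl, 488.0, 22.0)
    return np.where(wl > 600.0, 0.0, k)


def k_brown(wl: np.ndarray) -> np.ndarray:
    """Specific absorption of brown (senescent) pigment, decaying from blue."""
    wl = np.asarray(wl, dtype=float)
    k = 1.8 * np.exp(-(wl - 400.0) / 180.0)
    return np.where(wl > 1000.0, 0.0, k)


def k_water(wl: np.ndarray) -> np.ndarray:
    """Water absorption per cm of equivalent water thickness.

    Overtone bands near 970 and 1200 nm, strong bands at 1450 and 1940 nm,
    rising continuum toward 2500 nm.
    """
    wl = np.asarray(wl, dtype=float)
    k = (
        0.30 * _g(wl, 970.0, 35.0)
        + 1.30 * _g(wl, 1200.0, 45.0)
        + 30.0 * _g(wl, 1450.0, 60.0)
        + 120.0 * _g(wl, 1940.0, 90.0)
        + 60.0 * _g(wl, 2500.0, 200.0)
        + 0.004 * np.clip((wl - 800.0) / 100.0, 0.0, None)
    )
    return np.clip(k, 0.0, None)


def k_dry_matter(wl: np.ndarray) -> np.ndarray:
    """Dry-matter absorption per g cm-2: nearly transparent through the
    visible/NIR plateau (fresh-leaf NIR absorption is dominated by neither
    pigments nor dry matter), rising steeply into the SWIR with
    cellulose/lignin-like features near 1730, 2100 and 2300 nm."""
    wl = np.asarray(wl, dtype=float)
    k = (
        0.4
        + 30.0 / (1.0 + np.exp(-(wl - 1550.0) / 180.0))
        + 15.0 * _g(wl, 1730.0, 60.0)
        + 20.0 * _g(wl, 2100.0, 80.0)
        + 25.0 * _g(wl, 2300.0, 70.0)
    )
    return k


def soil_dry(wl: np.ndarray) -> np.ndarray:
    """Bright dry-soil reflectance continuum with water dips; peaks near 0.40."""
    wl = np.asarray(wl, dtype=float)
    base = 0.12 + 0.28 * (1.0 - np.exp(-(wl - 400.0) / 800.0))
    dips = 0.06 * _g(wl, 1450.0, 80.0) + 0.09 * _g(wl, 1940.0, 120.0)
    return np.clip(base - dips, 0.02, 1.0)


def soil_wet(wl: np.ndarray) -> np.ndarray:
    """Wet soil: darker overall, with deepened water absorption dips."""
    wl = np.asarray(wl, dtype=float)
    extra = 0.20 * _g(wl, 1450.0, 100.0) + 0.30 * _g(wl, 1940.0, 150.0)
    return np.clip(0.55 * soil_dry(wl) * (1.0 - extra), 0.0, 1.0)


# GF-1 WFV nominal band edges (Table of sensor specifications), micrometres
# converted to nm: B1 450-520, B2 520-590, B3 630-690, B4 770-890.
_BAND_EDGES_NM = {
    "b1": (450.0, 520.0),
    "b2": (520.0, 590.0),
    "b3": (630.0, 690.0),
    "b4": (770.0, 890.0),
}


def gaussian_srf(wl: np.ndarray) -> dict[str, np.ndarray]:
    """Synthetic Gaussian-lobe spectral response per band.

    Each lobe is centred on the nominal band and has a standard deviation
    of a quarter band width, truncated below 1e-3 relative response.
    """
    wl = np.asarray(wl, dtype=float)
    out: dict[str, np.ndarray] = {}
    for band, (lo, hi) in _BAND_EDGES_NM.items():
        center = 0.5 * (lo + hi)
        sigma = (hi - lo) / 4.0
        resp = _g(wl, center, sigma)
        resp[resp < 1e-3] = 0.0
        out[band] = resp
    return out
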