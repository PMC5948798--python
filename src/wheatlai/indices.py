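"""The ten vegetation indices of the retrieval strategy menu.

All formulas operate on surface reflectance in [0, 1].  ARVI is implemented
exactly in its printed form, (B4 - B3 - (B1 - B3)) / (B4 + B3 - (B1 - B3));
the numerator reduces algebraically to B4 - B1, which differs from the
standard gamma = 1 ARVI whose numerator is B4 - (2*B3 - B1).  The standard
form is available via ``arvi_standard=True``.  SAVI's soil factor L is the
canonical 0.5 unless overridden.
"""

from __future__ import annotations

import numpy as np

from .errors import UndefinedIndexError

VI_NAMES = ("RVI", "MSR", "GRVI", "NDVI", "GNDVI",
            "SAVI", "OSAVI", "TVI", "ARVI", "EVI")

_EPS = 1e-12


def _check(denom, name, bands):
    if np.isscalar(denom) or denom.ndim == 0:
        if abs(denom) < _EPS:
            raise UndefinedIndexError(
                f"{name} undefined: zero denominator for bands "
                f"B1={bands[..., 0]}, B2={bands[..., 1]}, "
                f"B3={bands[..., 2]}, B4={bands[..., 3]}"
            )


def compute_vi(name: str, bands, *, savi_l: float = 0.5,
               arvi_standard: bool = False):
    """Evaluate one vegetation index.

    ``bands`` is a BandSignature or an array whose last axis is
    (B1, B2, B3, B4).  Array inputs are evaluated elementwise with undefined
    values returned as NaN; scalar inputs raise UndefinedIndexError.
    """
    arr = bands.as_array() if hasattr(bands, "as_array") else np.asarray(bands, float)
    scalar = arr.ndim == 1
    b1, b2, b3, b4 = (arr[..., i] for i in range(4))

    def ratio(num, den):
        _check(den, name, arr)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num / den
        if not scalar:
            out = np.where(np.abs(den) < _EPS, np.nan, out)
        return out

    if name == "RVI":
        return ratio(b4, b3)
    if name == "MSR":
        rvi = ratio(b4, b3)
        return ratio(rvi - 1.0, rvi + 1.0)
    if name == "GRVI":
        return ratio(b4, b2) - 1.0
    if name == "NDVI":
        return ratio(b4 - b3, b3 + b4)
    if name == "GNDVI":
        return ratio(b4 - b2, b2 + b4)
    if name == "SAVI":
        return ratio((b4 - b3) * (1.0 + savi_l), b3 + b4 + savi_l)
    if name == "OSAVI":
        return ratio(1.16 * (b4 - b3), 0.16 + b4 + b3)
    if name == "TVI":
        return 0.5 * (120.0 * (b4 - b2) - 200.0 * (b3 - b2))
    if name == "ARVI":
        if arvi_standard:
            rb = 2.0 * b3 - b1
            return ratio(b4 - rb, b4 + rb)
        return ratio(b4 - b3 - (b1 - b3), b4 + b3 - (b1 - b3))
    if name == "EVI":
        return ratio(2.5 * (b4 - b3), b4 + 6.0 * b3 - 7.5 * b1 + 1.0)
    raise UndefinedIndexError(f"unknown vegetation index {name!r}")


def compute_all_vis(bands, **kwargs) -> dict:
    """All ten indices for one band signature; indices undefined for these
    band values are reported as NaN rather than dropped."""
    out = {}
    for name in VI_NAMES:
        try:
            out[name] = float(compute_vi(name, bands, **kwargs))
        except UndefinedIndexError:
            out[name] = float("nan")
    return out


def compute_vi_matrix(bands: np.ndarray, **kwargs) -> np.ndarray:
    """All ten indices for an array of signatures (..., 4) -> (..., 10)."""
    return np.stack([compute_vi(n, bands, **kwargs) for n in VI_NAMES], axis=-1)
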