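"""Scene raster I/O and per-pixel map production.

Scenes are stored as multi-band TIFF rasters (band-last float32 reflectance
or scaled integers) with a JSON sidecar carrying what a geo format would:
acquisition geometry, nodata value, and an optional integer scale factor.
Coordinate reference systems are passed through untouched and never
interpreted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigError, DataError
from .lut import LUT, Strategy, invert_batch
from .priors import FREE_NAMES
from .rtm import Geometry
from .scene import TrueScene


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_scene(scene: TrueScene, outdir: str | Path,
                write_truth: bool = True) -> Path:
    """Write observed (and truth) rasters plus the metadata sidecar; returns
    the observed raster path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs_path = outdir / "observed.tif"
    tifffile.imwrite(obs_path, scene.observed.astype(np.float32),
                     photometric="minisblack", planarconfig="contig")
    meta = {
        "stage": scene.stage,
        "tts": scene.geometry.tts, "tto": scene.geometry.tto,
        "psi": scene.geometry.psi, "skyl": scene.geometry.skyl,
        "seed": scene.seed,
        "nodata": None,
        "noise": {
            "band_relative_sigma": scene.noise.band_relative_sigma,
            "band_additive_sigma": scene.noise.band_additive_sigma,
            "lai_sigma": scene.noise.lai_sigma,
            "spad_sigma": scene.noise.spad_sigma,
        },
    }
    _sidecar(obs_path).write_text(json.dumps(meta, indent=2))
    if write_truth:
        for name, grid in scene.truth.items():
            tifffile.imwrite(outdir / f"truth_{name}.tif", grid.astype(np.float32))
    return obs_path


def read_scene(path: str | Path, metadata: str | Path | dict | None = None
               ) -> tuple[np.ma.MaskedArray, Geometry, dict]:
    """Read a 4-band reflectance raster and its geometry metadata.

    Returns (masked reflectance (rows, cols, 4) in [0, 1], Geometry, meta).
    Integer rasters must declare a "scale" in the metadata (stored values
    are divided by it); nodata pixels come back masked.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3 and data.shape[0] == 4 and data.shape[2] != 4:
        data = np.moveaxis(data, 0, 2)
    if data.ndim != 3 or data.shape[2] != 4:
        raise DataError(f"{path.name}: expected a 4-band raster, got shape {data.shape}")

    if metadata is None:
        metadata = _sidecar(path)
    if not isinstance(metadata, dict):
        mpath = Path(metadata)
        if not mpath.exists():
            raise DataError(f"scene metadata file {mpath} not found")
        metadata = json.loads(mpath.read_text())

    nodata = metadata.get("nodata")
    mask = np.zeros(data.shape, dtype=bool)
    if nodata is not None:
        mask = np.broadcast_to(np.any(data == nodata, axis=2)[..., None], data.shape).copy()

    if np.issubdtype(data.dtype, np.integer):
        scale = metadata.get("scale")
        if not scale:
            raise DataError(f"{path.name}: integer raster without a declared scale factor")
        values = data.astype(np.float64) / float(scale)
    else:
        values = data.astype(np.float64)
    if values[~mask].size and (values[~mask].min() < -1e-6 or values[~mask].max() > 1 + 1e-6):
        raise DataError(f"{path.name}: reflectance values outside [0, 1] after scaling")

    geom = Geometry(tts=float(metadata["tts"]), tto=float(metadata["tto"]),
                    psi=float(metadata["psi"]),
                    skyl=float(metadata.get("skyl", 0.1)))
    return np.ma.MaskedArray(values, mask=mask), geom, metadata


def produce_lai_map(
    observed: np.ndarray | np.ma.MaskedArray,
    geometry: Geometry,
    lut: LUT,
    strategy: Strategy,
    fraction: float = 0.10,
) -> np.ma.MaskedArray:
    """Per-pixel LUT inversion of a scene; masked/undefined pixels stay
    masked.  Refuses a LUT built for a different geometry."""
    g, lg = geometry, lut.geometry
    if not np.allclose([g.tts, g.tto, g.psi, g.skyl],
                       [lg.tts, lg.tto, lg.psi, lg.skyl]):
        raise ConfigError(
            f"LUT geometry (tts={lg.tts}, tto={lg.tto}, psi={lg.psi}, skyl={lg.skyl}) "
            f"does not match scene geometry (tts={g.tts}, tto={g.tto}, "
            f"psi={g.psi}, skyl={g.skyl})")

    arr = np.ma.filled(np.ma.asarray(observed), np.nan)
    rows, cols, nb = arr.shape
    if nb != 4:
        raise DataError("observed raster must have 4 bands")
    flat = arr.reshape(-1, 4)
    valid = np.all(np.isfinite(flat), axis=1)
    lai = np.full(flat.shape[0], np.nan)
    if valid.any():
        means, _ = invert_batch(flat[valid], strategy, lut, fraction)
        lai[valid] = means[:, FREE_NAMES.index("lai")]
    lai = lai.reshape(rows, cols)
    return np.ma.MaskedArray(lai, mask=~np.isfinite(lai))


def write_lai_map(lai: np.ma.MaskedArray, path: str | Path,
                  nodata: float = -9999.0) -> None:
    out = np.ma.filled(lai, nodata).astype(np.float32)
    tifffile.imwrite(path, out)
    _sidecar(Path(path)).write_text(json.dumps({"nodata": nodata}))
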