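"""Regenerate the vendored synthetic spectral fixtures from the analytic
recipes in wheatlai.synthspec.  Run from the repository root:

    python scripts/make_fixtures.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wheatlai import synthspec

DATA = Path(__file__).resolve().parents[1] / "src" / "wheatlai" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    # optical constants + soils at 5 nm (loaders resample to the 1 nm grid)
    wl = np.arange(400.0, 2501.0, 5.0)
    pd.DataFrame({
        "wavelength_nm": wl,
        "n": synthspec.refractive_index(wl),
        "k_cab": synthspec.k_chlorophyll(wl),
        "k_car": synthspec.k_carotenoid(wl),
        "k_brown": synthspec.k_brown(wl),
        "k_w": synthspec.k_water(wl),
        "k_m": synthspec.k_dry_matter(wl),
    }).to_csv(DATA / "optical_constants_synthetic.csv", index=False,
              float_format="%.6g")
    pd.DataFrame({
        "wavelength_nm": wl,
        "dry": synthspec.soil_dry(wl),
        "wet": synthspec.soil_wet(wl),
    }).to_csv(DATA / "soil_spectra_synthetic.csv", index=False,
              float_format="%.6g")

    # Gaussian-lobe SRF at 2 nm over the visible/NIR support
    wl_srf = np.arange(400.0, 1001.0, 2.0)
    srf = synthspec.gaussian_srf(wl_srf)
    pd.DataFrame({"wavelength_nm": wl_srf, **srf}).to_csv(
        DATA / "srf_gf1_wfv_synthetic.csv", index=False, float_format="%.6g")

    for f in sorted(DATA.glob("*.csv")):
        print(f"{f.name}: {f.stat().st_size / 1024:.1f} KiB")


if __name__ == "__main__":
    main()
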