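import numpy as np
import pytest

import wheatlai as w


@pytest.fixture(scope="session")
def constants():
    return w.load_optical_constants()


@pytest.fixture(scope="session")
def srf():
    return w.load_srf()


@pytest.fixture(scope="session")
def geometry():
    return w.Geometry(tts=46.0, tto=32.0, psi=90.0, skyl=0.1)


@pytest.fixture(scope="session")
def small_lut(constants, srf, geometry):
    """1,000-entry LUT shared by inversion tests."""
    return w.build_lut(w.default_priors(), geometry, srf, n=1000, seed=7,
                       constants=constants)


@pytest.fixture(scope="session")
def oracle_design():
    """Fixed 20-point parameter design spanning the prior ranges, used by
    the forward-model cross-check tests.  Columns: ni, cab, cw, cm, cbp,
    lai, alia, hspot, psoil."""
    rng = np.random.default_rng(20200517)
    n = 20
    design = np.column_stack([
        rng.uniform(1.2, 1.8, n),      # ni
        rng.uniform(25, 75, n),        # cab
        rng.uniform(0.60, 0.85, n),    # cw
        rng.uniform(0.003, 0.011, n),  # cm
        rng.uniform(0.0, 0.2, n),      # cbp
        rng.uniform(0.0, 8.0, n),      # lai
        rng.uniform(30, 80, n),        # alia
        rng.uniform(0.1, 0.5, n),      # hspot
        rng.uniform(0.5, 3.5, n),      # psoil
    ])
    return design
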