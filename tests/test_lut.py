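"""LUT construction, RRMSE costs and multi-solution inversion."""

import math

import numpy as np
import pandas as pd
import pytest

import wheatlai as w
from wheatlai.errors import ConfigError, UndefinedCostError
from wheatlai.indices import VI_NAMES, compute_vi_matrix
from wheatlai.lut import LUT, Strategy, rrmse_bands, rrmse_vi
from wheatlai.priors import FREE_NAMES


def _tiny_lut(n=10, seed=0, geometry=None):
    """Small synthetic LUT with random (not forward-simulated) bands, enough
    for inversion mechanics."""
    rng = np.random.default_rng(seed)
    geometry = geometry or w.Geometry(46.0, 32.0, 90.0, 0.1)
    params = w.sample_parameters(w.default_priors(), n, seed=seed)
    bands = rng.uniform(0.02, 0.8, (n, 4))
    vis = compute_vi_matrix(bands)
    return LUT(params=params, bands=bands, vis=vis, geometry=geometry)


class TestBuildLut:
    def test_seeded_determinism(self, constants, srf, geometry):
        a = w.build_lut(w.default_priors(), geometry, srf, n=100, seed=5,
                        constants=constants)
        b = w.build_lut(w.default_priors(), geometry, srf, n=100, seed=5,
                        constants=constants)
        assert len(a) == 100
        assert a.params.equals(b.params)
        np.testing.assert_array_equal(a.bands, b.bands)
        np.testing.assert_array_equal(a.vis, b.vis)

    def test_stored_vis_consistent_with_bands(self, small_lut):
        np.testing.assert_array_equal(small_lut.vis,
                                      compute_vi_matrix(small_lut.bands))

    def test_high_lai_brightens_nir_under_dark_soil(self, constants, srf, geometry):
        priors = w.default_priors()
        priors["psoil"] = w.ParameterPrior("psoil", "-", "fixed", mode=0.5)
        lut = w.build_lut(priors, geometry, srf, n=500, seed=11, constants=constants)
        lai = lut.params["lai"].to_numpy()
        b4 = lut.bands[:, 3]
        top = b4[lai >= np.quantile(lai, 0.9)].mean()
        bottom = b4[lai <= np.quantile(lai, 0.1)].mean()
        assert top > bottom

    def test_save_load_round_trip(self, small_lut, tmp_path):
        path = tmp_path / "lut.npz"
        small_lut.save(path)
        back = LUT.load(path)
        assert back.params.equals(small_lut.params)
        np.testing.assert_array_equal(back.bands, small_lut.bands)
        assert back.geometry == small_lut.geometry

    def test_csv_export_columns(self, small_lut, tmp_path):
        path = tmp_path / "lut.csv"
        small_lut.export_csv(path)
        cols = list(pd.read_csv(path, nrows=1).columns)
        assert len(cols) == 13 + 4 + 10


class TestCosts:
    def test_zero_residual(self):
        s = np.array([0.1, 0.2, 0.3, 0.4])
        assert rrmse_bands(s, s) == 0.0
        assert rrmse_vi(0.5, 0.5) == 0.0

    def test_single_band_relative_error(self):
        assert rrmse_bands(np.array([0.2, 1, 1, 1]), np.array([0.1, 1, 1, 1]),
                           subset=("B1",)) == pytest.approx(0.5, abs=1e-12)

    def test_two_band_hand_value(self):
        obs = np.array([0.2, 0.4, 1, 1])
        sim = np.array([0.1, 0.5, 1, 1])
        expect = math.sqrt((0.25 + 0.0625) / 2.0)
        assert rrmse_bands(obs, sim, subset=("B1", "B2")) == pytest.approx(
            expect, abs=1e-12)

    def test_vi_cost_symmetric_magnitude(self):
        assert rrmse_vi(0.5, 0.4) == pytest.approx(0.2, abs=1e-12)
        assert rrmse_vi(0.5, 0.6) == pytest.approx(0.2, abs=1e-12)

    def test_observed_below_guard_rejected(self):
        with pytest.raises(UndefinedCostError):
            rrmse_bands(np.array([0.0, 0.2, 0.3, 0.4]), np.full(4, 0.1),
                        subset=("B1", "B2"))
        with pytest.raises(UndefinedCostError):
            rrmse_vi(1e-9, 0.5)


class TestInvert:
    def test_single_entry_lut_returns_its_lai(self):
        lut = _tiny_lut(n=1)
        res = w.invert(np.array([0.9, 0.9, 0.9, 0.9]),
                       Strategy(kind="bands", bands=("B1", "B2", "B3", "B4")), lut)
        assert res.lai == pytest.approx(float(lut.params["lai"].iloc[0]))

    def test_exact_member_recovered(self):
        lut = _tiny_lut(n=10)
        k = 4
        strat = Strategy(kind="bands", bands=("B1", "B2", "B3", "B4"))
        res = w.invert(lut.bands[k], strat, lut, fraction=0.1)
        assert res.min_cost == 0.0
        assert res.n_averaged == 1
        assert res.lai == pytest.approx(float(lut.params["lai"].iloc[k]), abs=1e-12)

    def test_fraction_one_gives_prior_mean(self):
        lut = _tiny_lut(n=50)
        strat = Strategy(kind="bands", bands=("B2",))
        res = w.invert(np.array([0.3, 0.3, 0.3, 0.3]), strat, lut, fraction=1.0)
        assert res.lai == pytest.approx(float(lut.params["lai"].mean()), abs=1e-12)

    def test_permutation_invariance(self):
        lut = _tiny_lut(n=40, seed=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(40)
        shuffled = LUT(params=lut.params.iloc[perm].reset_index(drop=True),
                       bands=lut.bands[perm], vis=lut.vis[perm],
                       geometry=lut.geometry)
        obs = np.array([0.1, 0.2, 0.1, 0.5])
        for strat in (Strategy(kind="bands", bands=("B2", "B4")),
                      Strategy(kind="vi", vi="GNDVI")):
            r1 = w.invert(obs, strat, lut, fraction=0.2)
            r2 = w.invert(obs, strat, shuffled, fraction=0.2)
            assert r1.lai == pytest.approx(r2.lai, abs=1e-12)

    def test_agrees_with_brute_force(self):
        """invert vs an exhaustive nested-loop re-implementation using the
        scalar cost functions and an explicit (cost, index) sort."""
        lut = _tiny_lut(n=200, seed=3)
        rng = np.random.default_rng(4)
        obs_set = rng.uniform(0.05, 0.7, (5, 4))
        strategies = [Strategy(kind="bands", bands=("B1",)),
                      Strategy(kind="bands", bands=("B2", "B4")),
                      Strategy(kind="bands", bands=("B1", "B2", "B3", "B4")),
                      Strategy(kind="vi", vi="NDVI"),
                      Strategy(kind="vi", vi="TVI")]
        n_sel = math.ceil(0.1 * len(lut))
        for obs in obs_set:
            for strat in strategies:
                if strat.kind == "bands":
                    costs = [rrmse_bands(obs, lut.bands[i], strat.bands)
                             for i in range(len(lut))]
                else:
                    vi_obs = compute_vi_matrix(obs[None, :])[0, VI_NAMES.index(strat.vi)]
                    costs = [rrmse_vi(vi_obs, lut.vis[i, VI_NAMES.index(strat.vi)])
                             for i in range(len(lut))]
                order = sorted(range(len(lut)), key=lambda i: (costs[i], i))[:n_sel]
                expect = float(lut.params["lai"].iloc[order].mean())
                got = w.invert(obs, strat, lut, fraction=0.1)
                assert got.lai == pytest.approx(expect, abs=1e-12)
                assert got.min_cost == pytest.approx(costs[order[0]], abs=1e-12)

    def test_lut_member_self_consistency(self, small_lut):
        """Observations taken from LUT members rank their generating entry
        first with zero cost under every strategy kind."""
        for k in (0, 57, 431):
            obs = small_lut.bands[k]
            for strat in (Strategy(kind="bands", bands=("B1", "B2", "B3", "B4")),
                          Strategy(kind="vi", vi="GNDVI")):
                res = w.invert(obs, strat, small_lut, fraction=1.0 / len(small_lut))
                assert res.min_cost == 0.0
                assert res.lai == pytest.approx(
                    float(small_lut.params["lai"].iloc[k]), abs=1e-12)

    def test_posterior_mean_reports_all_free_parameters(self):
        lut = _tiny_lut(n=20)
        res = w.invert(np.array([0.2, 0.3, 0.2, 0.5]),
                       Strategy(kind="bands", bands=("B4",)), lut, fraction=0.5)
        assert set(res.posterior_means) == set(FREE_NAMES)

    def test_bad_fraction_rejected(self):
        lut = _tiny_lut(n=5)
        with pytest.raises(ConfigError):
            w.invert(np.full(4, 0.3), Strategy(kind="bands", bands=("B1",)),
                     lut, fraction=0.0)

    def test_invalid_strategy_rejected(self):
        with pytest.raises(ConfigError):
            Strategy(kind="bands", bands=())
        with pytest.raises(ConfigError):
            Strategy(kind="vi", vi="XYZ")
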