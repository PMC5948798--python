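"""Synthetic scene and plot generation."""

import numpy as np
import pandas as pd
import pytest

import wheatlai as w
from wheatlai.errors import ConfigError
from wheatlai.lut import simulate_bands
from wheatlai.priors import FREE_NAMES, ParameterPrior
from wheatlai.scene import StageProfile, stage_profile


@pytest.fixture(scope="module")
def small_noise_free_scene(constants, srf):
    profile = stage_profile("elongation")
    return w.generate_scene(profile, rows=12, cols=12, noise=w.NoiseModel.zero(),
                            seed=21, constants=constants, srf=srf)


class TestGenerateScene:
    def test_zero_noise_equals_forward_simulation(self, small_noise_free_scene,
                                                  constants, srf):
        sc = small_noise_free_scene
        flat = pd.DataFrame({n: sc.truth[n].ravel() for n in FREE_NAMES})
        g = sc.geometry
        flat["skyl"], flat["tts"], flat["tto"], flat["psi"] = g.skyl, g.tts, g.tto, g.psi
        sim = simulate_bands(flat, constants, srf, g).reshape(12, 12, 4)
        np.testing.assert_array_equal(sc.observed, sim)

    def test_seeded_determinism(self, constants, srf):
        profile = stage_profile("elongation")
        kw = dict(rows=8, cols=8, seed=5, constants=constants, srf=srf)
        a = w.generate_scene(profile, **kw)
        b = w.generate_scene(profile, **kw)
        np.testing.assert_array_equal(a.observed, b.observed)
        for name in FREE_NAMES:
            np.testing.assert_array_equal(a.truth[name], b.truth[name])

    def test_observations_clipped_to_unit_interval(self, constants, srf):
        noisy = w.NoiseModel(band_relative_sigma=0.3, band_additive_sigma=0.05)
        sc = w.generate_scene(stage_profile("grain_filling"), rows=10, cols=10,
                              noise=noisy, seed=6, constants=constants, srf=srf)
        assert sc.observed.min() >= 0.0
        assert sc.observed.max() <= 1.0

    def test_truth_fields_within_stage_ranges(self, small_noise_free_scene):
        lai = small_noise_free_scene.truth["lai"]
        assert lai.min() >= 0.5 and lai.max() <= 5.0
        assert np.all(small_noise_free_scene.truth["cbp"] == 0.0)

    def test_stage_profiles_differ_in_lai_and_senescence(self, constants, srf):
        e = w.generate_scene(stage_profile("elongation"), 16, 16,
                             noise=w.NoiseModel.zero(), seed=7,
                             constants=constants, srf=srf)
        gf = w.generate_scene(stage_profile("grain_filling"), 16, 16,
                              noise=w.NoiseModel.zero(), seed=7,
                              constants=constants, srf=srf)
        assert gf.truth["lai"].mean() > e.truth["lai"].mean()
        assert gf.truth["cbp"].min() >= 0.05

    def test_out_of_prior_profile_rejected_unless_forced(self):
        dists = dict(StageProfile(stage="elongation").distributions)
        dists["lai"] = ParameterPrior("lai", "-", "uniform", 0.0, 12.0)
        with pytest.raises(ConfigError):
            StageProfile(stage="elongation", distributions=dists)
        StageProfile(stage="elongation", distributions=dists,
                     allow_out_of_prior=True)  # does not raise

    def test_unknown_stage_rejected(self):
        with pytest.raises(ConfigError):
            stage_profile("harvest")


class TestGeneratePlots:
    def test_default_count_is_44(self, constants, srf):
        sc = w.generate_scene(stage_profile("elongation"), 60, 60,
                              noise=w.NoiseModel.zero(), seed=8,
                              constants=constants, srf=srf)
        plots = w.generate_plots(sc, noise=w.NoiseModel.zero(), seed=9)
        assert len(plots) == 44
        ids = {p.plot_id for p in plots}
        assert len(ids) == 44

    def test_zero_noise_measurements_exact(self, small_noise_free_scene):
        plots = w.generate_plots(small_noise_free_scene, n_plots=6,
                                 noise=w.NoiseModel.zero(), seed=10,
                                 min_spacing_px=2.0)
        for p in plots:
            r, c = int(p.y), int(p.x)
            assert p.lai_measured == small_noise_free_scene.truth["lai"][r, c]
            np.testing.assert_array_equal(p.bands,
                                          small_noise_free_scene.observed[r, c])

    def test_spad_round_trip_recovers_true_cab(self, small_noise_free_scene):
        plots = w.generate_plots(small_noise_free_scene, n_plots=6,
                                 noise=w.NoiseModel.zero(), seed=11,
                                 min_spacing_px=2.0)
        for p in plots:
            r, c = int(p.y), int(p.x)
            cab_true = small_noise_free_scene.truth["cab"][r, c]
            assert w.spad_to_cab(p.spad) == pytest.approx(cab_true, abs=1e-9)

    def test_minimum_spacing_enforced(self, constants, srf):
        sc = w.generate_scene(stage_profile("elongation"), 50, 50,
                              noise=w.NoiseModel.zero(), seed=12,
                              constants=constants, srf=srf)
        plots = w.generate_plots(sc, n_plots=20, noise=w.NoiseModel.zero(),
                                 seed=13, min_spacing_px=6.0)
        pts = np.array([[p.y, p.x] for p in plots])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 36.0

    def test_infeasible_spacing_reports_helpfully(self, small_noise_free_scene):
        with pytest.raises(ConfigError, match="spacing"):
            w.generate_plots(small_noise_free_scene, n_plots=100,
                             noise=w.NoiseModel.zero(), seed=14,
                             min_spacing_px=6.0)

    def test_noise_degrades_retrieval_monotonically(self, constants, srf,
                                                    geometry):
        """Increasing band noise does not decrease the pooled median LAI
        RMSE across all 25 strategies (3 noise levels x 3 seeds; the median
        is pooled over seeds because per-seed medians at these plot counts
        carry sampling noise of the same order as one noise step)."""
        lut = w.build_lut(w.default_priors(), geometry, srf, n=20_000,
                          seed=50, constants=constants)
        pooled = {0: [], 1: [], 3: []}
        for seed in (0, 1, 2):
            for mult in (0, 1, 3):
                nm = w.NoiseModel(band_relative_sigma=0.03 * mult,
                                  band_additive_sigma=0.005 * mult,
                                  lai_sigma=0.3, spad_sigma=1.5)
                sc = w.generate_scene(stage_profile("elongation"), 40, 40,
                                      noise=nm, seed=seed,
                                      constants=constants, srf=srf)
                plots = w.generate_plots(sc, 30, noise=nm, seed=seed + 10,
                                         min_spacing_px=4.0)
                scores = w.evaluate_strategies(plots, lut)
                pooled[mult].extend(s.rmse for s in scores)
        medians = [float(np.median(pooled[k])) for k in (0, 1, 3)]
        assert medians[0] <= medians[1] <= medians[2]

    def test_measured_lai_never_negative(self, constants, srf):
        sc = w.generate_scene(stage_profile("elongation"), 30, 30,
                              noise=w.NoiseModel.zero(), seed=15,
                              constants=constants, srf=srf)
        plots = w.generate_plots(sc, n_plots=30,
                                 noise=w.NoiseModel(lai_sigma=3.0), seed=16,
                                 min_spacing_px=3.0)
        assert all(p.lai_measured >= 0 for p in plots)
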