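"""Background K0, particle intensity, calibration fits, stoichiometry."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import nanospt as n
from nanospt import intensity as inten
from nanospt.intensity import (
    ExcludedTrackError,
    NoCellError,
    first_step_frame,
)
from nanospt.simulate import cell_mask_truth


def one_frame_stack(img):
    return n.ImageStack(frames=np.asarray(img)[None].astype(float))


class TestBackgroundK0:
    def test_hand_quantile_1_to_100(self):
        img = np.arange(1, 101, dtype=float).reshape(10, 10)
        stack = one_frame_stack(img)
        bg = inten.estimate_background(stack, np.ones((10, 10), bool), None, q=0.80)
        assert np.isclose(bg.k0[0], 80.2)  # linear-interpolation convention

    def test_constant_background(self):
        stack = n.ImageStack(frames=np.full((5, 8, 8), 37.0))
        bg = inten.estimate_background(stack, np.ones((8, 8), bool))
        assert np.allclose(bg.k0, 37.0)

    def test_exclusion_makes_k0_independent_of_particles(self):
        base = np.full((20, 20), 50.0)
        with_particle = base.copy()
        with_particle[9:12, 9:12] = 60000.0  # saturated spot
        det = pd.DataFrame({"frame": [1], "x_px": [10.0], "y_px": [10.0]})
        k_plain = inten.estimate_background(
            one_frame_stack(base), np.ones((20, 20), bool)).k0[0]
        k_excl = inten.estimate_background(
            one_frame_stack(with_particle), np.ones((20, 20), bool), det).k0[0]
        assert k_excl == k_plain

    def test_all_excluded_fails(self):
        det = pd.DataFrame({"frame": [1], "x_px": [1.0], "y_px": [1.0]})
        with pytest.raises(ValueError, match="excluded"):
            inten.estimate_background(one_frame_stack(np.ones((3, 3))),
                                      np.ones((3, 3), bool), det)

    def test_quantile_bounds(self):
        with pytest.raises(ValueError):
            inten.estimate_background(one_frame_stack(np.ones((3, 3))),
                                      np.ones((3, 3), bool), None, q=1.5)


class TestSegmentation:
    def test_disc_iou(self):
        c = n.SimulationConfig(fov_px=96, frame_count=30, seed=2,
                               particle_density_per_um2=0.5)
        stack, _ = n.simulate_receptor_movie(c)
        mask = n.segment_cell(stack)
        truth = cell_mask_truth(c)
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.9

    def test_uniform_image_fails(self):
        with pytest.raises(NoCellError):
            n.segment_cell(n.ImageStack(frames=np.full((3, 16, 16), 7.0)))

    def test_mask_area_invariant_to_particles(self):
        base = dict(fov_px=96, frame_count=30, seed=2)
        c0 = n.SimulationConfig(particle_density_per_um2=0.0, **base)
        c1 = n.SimulationConfig(particle_density_per_um2=0.8, **base)
        a0 = n.segment_cell(n.simulate_receptor_movie(c0)[0]).sum()
        a1 = n.segment_cell(n.simulate_receptor_movie(c1)[0]).sum()
        assert abs(a1 - a0) / a0 <= 0.02


class TestStepDetection:
    def test_clean_single_step(self):
        trace = np.array([980.0] * 30 + [0.0] * 20)
        assert first_step_frame(trace, min_drop_frac=0.5) == 31

    def test_no_step_on_constant(self):
        assert first_step_frame(np.full(50, 980.0)) is None

    def test_multistep_staircase_returns_first(self):
        trace = np.array([5, 5, 4, 4, 3] + [2] * 19 + [1] * 16, float) * 980
        assert first_step_frame(trace) == 3

    def test_noisy_single_step(self, rng):
        trace = np.concatenate([980 + 40 * rng.standard_normal(60),
                                0 + 40 * rng.standard_normal(40)])
        d = first_step_frame(trace, min_drop_frac=0.5)
        assert d is not None and abs(d - 61) <= 1


class TestParticleIntensity:
    def _movie_single(self, k, **kw):
        base = dict(fov_px=48, cell_radius_frac=None, n_particles=1,
                    frame_count=30, mobile_fraction=0.0, monomer_sd_au=0.0,
                    shot_noise=False, read_noise_sd_au=0.0,
                    bleach_lifetime_s=np.inf,
                    stoichiometry_pmf={k: 1.0}, seed=5)
        base.update(kw)
        return n.SimulationConfig(**base)

    def test_noise_free_monomer_returns_reference(self):
        c = self._movie_single(1)
        stack, gt = n.simulate_receptor_movie(c)
        tracks = n.detect_and_track(stack)
        bg = inten.estimate_background(stack, np.ones((48, 48), bool), tracks)
        val = inten.particle_intensity(tracks, stack, bg, window_frames=20,
                                       psf_sigma_px=1.0)
        assert abs(val - 980.0) <= 5.0

    def test_noise_free_trimer_is_three_monomers(self):
        c = self._movie_single(3)
        stack, gt = n.simulate_receptor_movie(c)
        tracks = n.detect_and_track(stack)
        bg = inten.estimate_background(stack, np.ones((48, 48), bool), tracks)
        val = inten.particle_intensity(tracks, stack, bg, psf_sigma_px=1.0)
        assert abs(val - 3 * 980.0) <= 15.0

    def test_pure_background_gives_zero(self):
        stack = n.ImageStack(frames=np.full((25, 32, 32), 100.0))
        bg = inten.estimate_background(stack, np.ones((32, 32), bool))
        track = pd.DataFrame({"track_id": 0, "frame": np.arange(1, 26),
                              "x_px": 16.0, "y_px": 16.0})
        val = inten.particle_intensity(track, stack, bg, psf_sigma_px=None,
                                       truncate_at_step=False)
        assert val == 0.0

    def test_border_window_excluded(self):
        stack = n.ImageStack(frames=np.full((25, 32, 32), 100.0))
        bg = inten.estimate_background(stack, np.ones((32, 32), bool))
        track = pd.DataFrame({"track_id": 0, "frame": np.arange(1, 26),
                              "x_px": 0.2, "y_px": 16.0})
        with pytest.raises(ExcludedTrackError, match="border"):
            inten.particle_intensity(track, stack, bg)

    def test_short_track_excluded(self):
        stack = n.ImageStack(frames=np.full((5, 32, 32), 100.0))
        bg = inten.estimate_background(stack, np.ones((32, 32), bool))
        track = pd.DataFrame({"track_id": 0, "frame": np.arange(1, 6),
                              "x_px": 16.0, "y_px": 16.0})
        with pytest.raises(ExcludedTrackError, match="shorter"):
            inten.particle_intensity(track, stack, bg, window_frames=20)


class TestCalibrationFits:
    def test_gaussian_recovery_reference(self, rng):
        x = rng.normal(980.0, 89.0, size=5000)
        cal = n.fit_monomer_reference(x)
        assert abs(cal.mu_mono - 980.0) <= 3 * 89.0 / np.sqrt(5000)
        assert abs(cal.sigma_mono - 89.0) <= 5.0

    def test_gaussian_recovery_tight(self, rng):
        x = rng.normal(500.0, 50.0, size=10_000)
        cal = n.fit_monomer_reference(x)
        assert 498.5 <= cal.mu_mono <= 501.5

    def test_histogram_method_agrees(self, rng):
        x = rng.normal(980.0, 89.0, size=5000)
        mle = n.fit_monomer_reference(x)
        hist = n.fit_monomer_reference(x, method="histogram")
        assert abs(hist.mu_mono - mle.mu_mono) <= 10.0

    def test_degenerate_constant_input(self):
        cal = n.fit_monomer_reference(np.full(100, 700.0))
        assert cal.mu_mono == 700.0 and cal.sigma_mono == 0.0
        assert cal.degenerate

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError, match="50"):
            n.fit_monomer_reference(np.ones(10) * 980)

    def test_photobleach_recovery_5s(self, rng):
        t = rng.exponential(5.0, size=5000)
        fit = n.fit_photobleaching(t, frame_interval_s=0.1)
        assert abs(fit.tau0_s - 5.0) <= 3 * 5.0 / np.sqrt(5000)
        assert abs(fit.tau0_frames - 50.0) <= 3.0
        assert fit.exponential_like

    def test_photobleach_recovery_2s(self, rng):
        t = rng.exponential(2.0, size=5000)
        fit = n.fit_photobleaching(t, frame_interval_s=0.1)
        assert 1.9 <= fit.tau0_s <= 2.1

    def test_degenerate_point_mass_flagged(self):
        fit = n.fit_photobleaching(np.full(200, 3.0), 0.1)
        assert not fit.exponential_like

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            n.fit_photobleaching(np.linspace(-1, 5, 200), 0.1)

    def test_window_check_warns_when_window_too_long(self):
        short = inten.PhotobleachFit(tau0_s=1.5, tau0_frames=15, n_traces=500)
        assert not n.check_window_vs_bleaching(20, short)
        ok = inten.PhotobleachFit(tau0_s=5.0, tau0_frames=50, n_traces=500)
        assert n.check_window_vs_bleaching(20, ok)


class TestStoichiometry:
    @pytest.mark.parametrize("intensity,ratio,count", [
        (980.0, 1.0, 1),
        (1960.0, 2.0, 2),
        (3219.0, 3219.0 / 980.0, 3),  # ratio ~3.28 -> nanocluster
    ])
    def test_ratio_and_count(self, intensity, ratio, count):
        calib = inten.CalibrationResult(mu_mono=980.0, sigma_mono=89.0,
                                        n_particles=5000)
        r, c = n.estimate_stoichiometry(intensity, calib)
        assert np.isclose(r, ratio)
        assert c == count

    def test_half_integer_rounds_to_even(self):
        calib = inten.CalibrationResult(mu_mono=1000.0, sigma_mono=0.0,
                                        n_particles=100)
        assert n.estimate_stoichiometry(2500.0, calib)[1] == 2
        assert n.estimate_stoichiometry(3500.0, calib)[1] == 4

    def test_nonpositive_intensity_excluded(self):
        calib = inten.CalibrationResult(mu_mono=980.0, sigma_mono=89.0,
                                        n_particles=100)
        with pytest.raises(ExcludedTrackError):
            n.estimate_stoichiometry(0.0, calib)

    def test_classify_all_mono_dimer(self):
        df = pd.DataFrame({"receptor_count": [1, 1, 2],
                           "mean_intensity_au": [980, 1000, 1900]})
        g = n.classify_aggregation(df)
        assert g.pct_mono_dimer == 100.0 and g.pct_nanocluster == 0.0

    def test_classify_all_nanocluster_and_msi(self):
        df = pd.DataFrame({"receptor_count": [3, 4, 5],
                           "mean_intensity_au": [3000.0, 4000.0, 5000.0]})
        g = n.classify_aggregation(df)
        assert g.pct_nanocluster == 100.0
        assert np.isclose(g.msi_au, 4000.0)

    def test_classify_empty_rejected(self):
        with pytest.raises(ValueError):
            n.classify_aggregation(pd.DataFrame(columns=["receptor_count",
                                                         "mean_intensity_au"]))

    def test_mixture_fraction_recovery_fast_path(self):
        c = n.SimulationConfig(
            fov_px=64, cell_radius_frac=None, n_particles=800,
            frame_count=60, seed=13,
            stoichiometry_pmf={1: 0.40, 2: 0.30, 3: 0.20, 4: 0.10})
        tracks, gt = n.simulate_trajectories(c)
        calib = inten.CalibrationResult(mu_mono=980.0, sigma_mono=89.0,
                                        n_particles=5000)
        parts = n.summarize_particles(tracks, calib)
        eff = gt.counts_alive_at(1)
        visible = eff[eff > 0]
        true_nano = 100.0 * (visible >= 3).mean()
        est = n.classify_aggregation(parts)
        assert abs(est.pct_nanocluster - true_nano) <= 5.0


class TestMonomerCalibrationPipeline:
    def test_calibrate_monomer_recovers_reference(self):
        c = n.SimulationConfig(fov_px=64, cell_radius_frac=None,
                               n_particles=2000, seed=31)
        tracks, _ = n.simulate_calibration_tracks(c)
        calib, bleach = n.calibrate_monomer(tracks, c.frame_interval_s)
        assert abs(calib.mu_mono - 980.0) <= 6.0
        assert abs(calib.sigma_mono - 89.0) <= 10.0
        assert abs(bleach.tau0_s - 5.0) <= 0.25
        assert n.check_window_vs_bleaching(20, bleach)
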