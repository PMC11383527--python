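"""Generator correctness: distributions, determinism, photophysics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import nanospt as n
from nanospt.simulate import NEVER


def cfg(**kw):
    base = dict(fov_px=64, cell_radius_frac=None, seed=1)
    base.update(kw)
    return n.SimulationConfig(**base)


class TestConfigValidation:
    def test_pmf_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cfg(stoichiometry_pmf={1: 0.5, 2: 0.4}).validate()

    def test_mobile_fraction_bounds(self):
        with pytest.raises(ValueError, match="mobile_fraction"):
            cfg(mobile_fraction=1.2).validate()

    def test_positive_rates(self):
        with pytest.raises(ValueError):
            cfg(frame_interval_s=0.0).validate()

    def test_density_cap_refused(self):
        c = cfg(fov_px=512, particle_density_per_um2=100.0, particle_cap=1000)
        with pytest.raises(ValueError, match="cap"):
            n.simulate_trajectories(c)


class TestMovie:
    def test_empty_field_is_pure_background(self):
        c = cfg(particle_density_per_um2=0.0, frame_count=5,
                shot_noise=False, read_noise_sd_au=0.0)
        stack, gt = n.simulate_receptor_movie(c)
        assert gt.n_particles == 0
        assert np.all(stack.frames == int(c.background_level_au))

    def test_immobile_monomer_constant_window_sum(self):
        c = cfg(n_particles=1, frame_count=40, mobile_fraction=0.0,
                shot_noise=False, read_noise_sd_au=0.0, monomer_sd_au=0.0,
                bleach_lifetime_s=np.inf)
        stack, gt = n.simulate_receptor_movie(c)
        x = int(round(gt.particles.x0_px[0]))
        y = int(round(gt.particles.y0_px[0]))
        sums = stack.frames[:, y - 1:y + 2, x - 1:x + 2].sum(axis=(1, 2))
        assert sums.std() <= 1.0  # uint16 rounding only
        assert sums.mean() > 9 * c.background_level_au

    def test_kmer_peak_is_k_times_monomer(self):
        base = dict(n_particles=1, frame_count=1, mobile_fraction=0.0,
                    shot_noise=False, read_noise_sd_au=0.0, monomer_sd_au=0.0,
                    bleach_lifetime_s=np.inf, seed=3)
        s1, g1 = n.simulate_receptor_movie(cfg(stoichiometry_pmf={1: 1.0}, **base))
        s3, g3 = n.simulate_receptor_movie(cfg(stoichiometry_pmf={3: 1.0}, **base))
        assert np.allclose(g1.particles.x0_px, g3.particles.x0_px)
        bg = base_bg = 100.0
        a1 = s1.frames[0].astype(float) - bg
        a3 = s3.frames[0].astype(float) - base_bg
        assert abs(a3.sum() - 3 * a1.sum()) <= 0.01 * 3 * a1.sum() + 20

    def test_stoichiometry_histogram_matches_pmf(self):
        pmf = {1: 0.6, 2: 0.2, 4: 0.2}
        c = cfg(n_particles=1000, frame_count=1, stoichiometry_pmf=pmf, seed=8)
        _, gt = n.simulate_receptor_movie(c)
        counts = gt.particles.true_count.value_counts()
        for k, p in pmf.items():  # exact binomial 99% central bounds
            lo = sps.binom.ppf(0.005, 1000, p)
            hi = sps.binom.ppf(0.995, 1000, p)
            assert lo <= counts.get(k, 0) <= hi


class TestTrajectories:
    def test_static_without_motion_or_noise(self):
        c = cfg(n_particles=5, frame_count=50, d_mobile_um2_s=0.0,
                loc_noise_sd_um=0.0, shot_noise=False, read_noise_sd_au=0.0)
        tracks, _ = n.simulate_trajectories(c)
        for _, sub in tracks.groupby("track_id"):
            assert sub.x_px.nunique() == 1 and sub.y_px.nunique() == 1

    def test_brownian_mean_squared_step(self):
        c = cfg(fov_px=4000, n_particles=40, frame_count=500,
                mobile_fraction=1.0, loc_noise_sd_um=0.0,
                shot_noise=False, read_noise_sd_au=0.0, seed=4)
        _, gt = n.simulate_trajectories(c)
        pos_um = gt.positions_px * c.pixel_size_um
        steps = np.diff(pos_um, axis=1)
        ms = float(np.mean(np.sum(steps ** 2, axis=2)))  # ~2e4 steps
        expected = 4 * c.d_mobile_um2_s * c.frame_interval_s
        assert abs(ms - expected) <= 0.05 * expected

    def test_kmer_intensity_linear_before_bleach(self):
        c = cfg(n_particles=10, frame_count=30, stoichiometry_pmf={4: 1.0},
                monomer_sd_au=0.0, shot_noise=False, read_noise_sd_au=0.0,
                bleach_lifetime_s=np.inf)
        tracks, _ = n.simulate_trajectories(c)
        assert np.allclose(tracks.intensity_au, 4 * c.monomer_mean_au)

    def test_fluorophore_count_monotone_in_time(self):
        c = cfg(n_particles=100, frame_count=200, seed=6)
        _, gt = n.simulate_trajectories(c)
        assert np.all(np.diff(gt.amplitudes_au, axis=1) <= 1e-9)

    def test_counts_alive_accounts_for_prebleached(self):
        c = cfg(n_particles=300, frame_count=100, stoichiometry_pmf={2: 1.0})
        _, gt = n.simulate_trajectories(c)
        alive = gt.counts_alive_at(1)
        dark = gt.fluorophores.first_dark_frame == 1
        assert alive.sum() == len(gt.fluorophores) - dark.sum()


class TestCalibrationPhotophysics:
    def test_no_bleach_when_lifetime_infinite(self):
        c = cfg(n_particles=50, frame_count=100, bleach_lifetime_s=np.inf)
        _, gt = n.simulate_calibration_tracks(c)
        assert np.all(gt.fluorophores.first_dark_frame == NEVER)
        assert np.all(np.diff(gt.amplitudes_au, axis=1) == 0)

    def test_bleach_times_exponential_ks(self):
        c = cfg(n_particles=5000, frame_count=500, seed=9)
        _, gt = n.simulate_calibration_tracks(c)
        t = gt.fluorophores.bleach_time_s.to_numpy()
        stat = sps.kstest(t, sps.expon(scale=c.bleach_lifetime_s).cdf).statistic
        assert stat < 1.63 / np.sqrt(len(t))  # 1% critical value

    def test_single_downward_step_per_trace(self):
        c = cfg(n_particles=200, frame_count=300, monomer_sd_au=0.0,
                shot_noise=False, read_noise_sd_au=0.0)
        tracks, _ = n.simulate_calibration_tracks(c)
        for _, sub in tracks.groupby("track_id"):
            v = sub.sort_values("frame").intensity_au.to_numpy()
            drops = np.flatnonzero(np.diff(v) < -1e-9)
            assert len(drops) <= 1
            if len(drops):
                assert np.all(v[drops[0] + 1:] == 0.0)


class TestCellTracks:
    def test_full_bias_is_straight_plus_x(self):
        tracks, _ = n.simulate_cell_tracks(5, 20, step_um=2.0, bias=1.0, seed=2)
        for _, sub in tracks.groupby("cell_id"):
            assert np.allclose(np.diff(sub.x_um), 2.0)
            assert np.allclose(sub.y_um, 0.0)

    def test_unbiased_null_fmi(self):
        tracks, _ = n.simulate_cell_tracks(200, 60, step_um=5.0, bias=0.0, seed=3)
        summary = n.group_chemotaxis_summary(tracks)
        assert abs(summary["fmi_x_mean"]) < 0.05

    def test_partial_bias_matches_independent_resimulation(self):
        # brute-force oracle: an independent reimplementation of the walk
        def oracle(n_cells, n_steps, step, bias, seed, persistence=1.0):
            rng = np.random.default_rng(seed)
            th = rng.random(n_cells) * 2 * np.pi
            d = np.stack([np.cos(th), np.sin(th)], 1)
            fmis = np.zeros(n_cells)
            pos = np.zeros((n_cells, 2))
            acc = np.zeros(n_cells)
            for _ in range(n_steps):
                phi = rng.random(n_cells) * 2 * np.pi
                r = d + persistence * np.stack([np.cos(phi), np.sin(phi)], 1)
                r /= np.linalg.norm(r, axis=1, keepdims=True)
                d = (1 - bias) * r + bias * np.array([1.0, 0.0])
                d /= np.linalg.norm(d, axis=1, keepdims=True)
                pos += step * d
                acc += step
            return float(np.mean(pos[:, 0] / acc))

        tracks, _ = n.simulate_cell_tracks(400, 50, step_um=3.0, bias=0.5, seed=7)
        ours = n.group_chemotaxis_summary(tracks)["fmi_x_mean"]
        ref = oracle(400, 50, 3.0, 0.5, seed=1234)
        assert abs(ours - ref) < 0.04  # Monte-Carlo error at n=400

    def test_bias_bounds(self):
        with pytest.raises(ValueError, match="bias"):
            n.simulate_cell_tracks(2, 2, bias=1.5)


class TestDeterminism:
    def test_movie_bit_identical_under_seed(self):
        c = cfg(n_particles=20, frame_count=10, seed=11)
        s1, g1 = n.simulate_receptor_movie(c)
        s2, g2 = n.simulate_receptor_movie(dataclasses.replace(c))
        assert np.array_equal(s1.frames, s2.frames)
        pd.testing.assert_frame_equal(g1.particles, g2.particles)

    def test_trajectories_bit_identical_under_seed(self):
        c = cfg(n_particles=20, frame_count=50, seed=11)
        t1, _ = n.simulate_trajectories(c)
        t2, _ = n.simulate_trajectories(dataclasses.replace(c))
        pd.testing.assert_frame_equal(t1, t2)

    def test_seed_changes_output(self):
        t1, _ = n.simulate_trajectories(cfg(n_particles=20, seed=1, frame_count=10))
        t2, _ = n.simulate_trajectories(cfg(n_particles=20, seed=2, frame_count=10))
        assert not np.allclose(t1.x_px, t2.x_px)
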