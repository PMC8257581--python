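"""Tests for ageing increments, MSD, first passage and oscillations."""

import math

import numpy as np
import pytest

import satwalk as sw
from satwalk import ensemble as es

from conftest import make_track, triangle_track


class TestIncrements:
    def test_ballistic_is_quadratic_at_all_ages(self):
        v = 3.0
        t = np.arange(2001, dtype=float)
        paths = np.tile(v * t, (4, 1))
        cur = es.increments(paths, ages=[0, 500, 1000], window=200,
                            lags=[1, 5, 20, 100])
        for a in range(3):
            np.testing.assert_allclose(cur.values[a], (v * cur.lags) ** 2,
                                       rtol=1e-9)

    def test_simple_walk_shows_no_ageing(self):
        paths = sw.simulate_ensemble(sw.WalkParams(k=0.0, beta=0.0), 4000,
                                     600, seed=13)
        cur = es.increments(paths, ages=[0, 1000, 3000], window=500,
                            lags=[2, 8, 30, 100, 160])
        # I(T, t) ~ 2 D t with 2D = 1, independent of the age T
        np.testing.assert_allclose(cur.values, np.tile(cur.lags, (3, 1)),
                                   rtol=0.1)
        assert es.ageing_z(cur) < 3.0

    def test_attractive_walk_ages(self):
        paths = sw.simulate_ensemble(sw.WalkParams(k=0.5, beta=-2.0), 4000,
                                     400, seed=14)
        cur = es.increments(paths, ages=[0, 3000], window=500,
                            lags=[2, 8, 30, 100, 160])
        assert es.ageing_z(cur) > 3.0

    def test_sem_shrinks_with_ensemble_size(self):
        p = sw.WalkParams(k=0.0, beta=-1.0)
        small = es.increments(sw.simulate_ensemble(p, 500, 100, seed=1),
                              ages=[0], window=100, lags=[10, 50])
        big = es.increments(sw.simulate_ensemble(p, 500, 900, seed=1),
                            ages=[0], window=100, lags=[10, 50])
        assert np.all(big.sem < small.sem)

    def test_window_longer_than_trajectory(self):
        paths = np.zeros((3, 50))
        with pytest.raises(sw.InsufficientDataError):
            es.increments(paths, ages=[0], window=45, lags=[10])

    def test_track_interface_windowing(self, control_dataset):
        cur = es.increments_from_tracks(control_dataset.tracks,
                                        ages_h=(0.0, 12.0), window_h=12.0)
        assert cur.lags.max() <= 4.0 + 1e-9  # cut at window / 3
        assert np.all(cur.values >= 0)


class TestMsd:
    def test_stationary_zero(self):
        times, vals, _ = es.msd(np.zeros((5, 100)))
        np.testing.assert_allclose(vals, 0.0)

    def test_simple_2d_walk_slope_one(self):
        paths = sw.simulate_ensemble(sw.WalkParams(k=0.0, beta=0.0, dim=2),
                                     2000, 500, seed=15)
        times, vals, _ = es.msd(paths)
        fit = sw.fit_power_exponent(times[1:], vals[1:], (10, 2000))
        assert fit.exponent == pytest.approx(1.0, abs=0.1)

    def test_attraction_uniformly_slows_spreading(self):
        free = sw.simulate_ensemble(sw.WalkParams(k=0.0, beta=0.0, dim=2),
                                    2000, 400, seed=16)
        attr = sw.simulate_ensemble(sw.WalkParams(k=0.0, beta=-2.5, dim=2),
                                    2000, 400, seed=16)
        _, v_free, _ = es.msd(free)
        _, v_attr, _ = es.msd(attr)
        assert np.all(v_attr[100:] < v_free[100:])

    def test_unsquared_option(self):
        paths = np.tile(np.arange(50.0), (3, 1))
        _, vals, _ = es.msd(paths, squared=False)
        np.testing.assert_allclose(vals, np.arange(50.0), rtol=1e-12)


class TestSurvival:
    def test_adjacent_target_first_step(self):
        # symmetric start: half of the first steps hit a target at r = 1
        c = es.survival_probability(sw.WalkParams(k=0.0, beta=0.0), 1, 20000,
                                    10, seed=17)
        assert c.S[0] == 1.0
        assert c.S[1] == pytest.approx(0.5, abs=0.02)
        assert np.all(np.diff(c.S) <= 0)

    def test_ballistic_walker_hits_at_r(self):
        # k so large the walk is deterministic; aimed at the target
        c = es.survival_probability(sw.WalkParams(k=40.0, beta=0.0), 7, 50,
                                    20, seed=18, initial_direction=1)
        assert np.all(c.S[:7] == 1.0)
        assert np.all(c.S[7:] == 0.0)

    def test_memoryless_tail_near_half(self):
        c = es.survival_probability(sw.WalkParams(k=0.0, beta=0.0), 10, 3000,
                                    30000, seed=19)
        fit = es.survival_exponent(c, seed=0)
        assert fit.exponent == pytest.approx(0.5, abs=0.1)

    def test_sem_shrinks_with_walkers(self):
        p = sw.WalkParams(k=0.0, beta=0.0)
        a = es.survival_probability(p, 5, 500, 2000, seed=20)
        b = es.survival_probability(p, 5, 5000, 2000, seed=20)
        mid = 200
        assert b.sem[mid] < a.sem[mid]


class TestExponentFit:
    def test_exact_power_law(self):
        t = np.geomspace(1, 1000, 40)
        fit = sw.fit_power_exponent(t, 2.7 * t ** -1.37, (1, 1000))
        assert fit.exponent == pytest.approx(-1.37, abs=1e-12)
        assert fit.good_fit

    def test_exponential_flagged_as_bad(self):
        t = np.geomspace(1, 100, 40)
        fit = sw.fit_power_exponent(t, np.exp(-t / 10.0), (1, 100))
        assert not fit.good_fit

    def test_window_with_zeros_refused(self):
        t = np.arange(1.0, 20.0)
        y = np.ones_like(t)
        y[5] = 0.0
        with pytest.raises(sw.FitError):
            sw.fit_power_exponent(t, y, (1, 19))

    def test_too_few_points(self):
        with pytest.raises(sw.FitError):
            sw.fit_power_exponent([1, 2, 3], [1, 2, 3], (1, 3))


class TestThetaTheory:
    def test_values(self):
        assert sw.theta_theory(0.0) == 0.5
        assert sw.theta_theory(-math.log(2.0)) == pytest.approx(1.0, rel=1e-12)

    def test_strictly_decreasing_in_beta(self):
        betas = np.linspace(-3, 3, 25)
        theta = [sw.theta_theory(b) for b in betas]
        assert np.all(np.diff(theta) < 0)


class TestOscillations:
    def test_triangle_wave_exact(self):
        amp, period = 40.0, 8.0
        s = sw.detect_oscillations(triangle_track(amp, period), min_excursion=10.0)
        assert s.n_reversals >= 6
        np.testing.assert_allclose(s.amplitudes, amp, rtol=1e-9)
        np.testing.assert_allclose(s.periods, period, rtol=1e-9)
        np.testing.assert_allclose(s.ratios, amp / period, rtol=1e-9)

    def test_constant_position_empty(self):
        t = np.arange(0.0, 10.0, 0.1)
        s = sw.detect_oscillations(make_track(t, np.full(t.size, 3.0)))
        assert s.n_reversals == 0
        assert s.amplitudes.size == 0

    def test_bouncing_runner_ratio_near_half_speed(self, control_dataset):
        """A runner bouncing at speed v covers A = v T/2 per half period,
        so A/T stays near v/2 while amplitudes grow."""
        model = sw.PRESETS["control"]
        v = model.L_ref_um / model.mean_jump_h
        ratios = np.concatenate([
            sw.detect_oscillations(tr, min_excursion=10.0).ratios
            for tr in control_dataset.tracks])
        assert ratios.size > 50
        assert 0.5 * v / 2 < np.median(ratios) < 2.0 * v / 2


class TestEffectiveDiffusion:
    def test_exact_line_2d(self):
        t = np.arange(0.0, 100.0)
        assert sw.effective_diffusion(t, 4.0 * 2.5 * t, (0, 99), dim=2) == \
            pytest.approx(2.5, rel=1e-12)

    def test_simple_1d_walk_half(self):
        paths = sw.simulate_ensemble(sw.WalkParams(k=0.0, beta=0.0), 2000,
                                     500, seed=23)
        times, vals, _ = es.msd(paths)
        D = sw.effective_diffusion(times, vals, (100, 2000), dim=1)
        assert D == pytest.approx(0.5, rel=0.1)

    def test_attraction_reduces_diffusion(self):
        free = sw.simulate_ensemble(sw.WalkParams(k=0.0, beta=0.0, dim=2),
                                    3000, 300, seed=24)
        attr = sw.simulate_ensemble(sw.WalkParams(k=0.0, beta=-2.5, dim=2),
                                    3000, 300, seed=24)
        t_f, v_f, _ = es.msd(free)
        t_a, v_a, _ = es.msd(attr)
        D_f = sw.effective_diffusion(t_f, v_f, (500, 3000), dim=2)
        D_a = sw.effective_diffusion(t_a, v_a, (500, 3000), dim=2)
        assert D_a / D_f < 1.0
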