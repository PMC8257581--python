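"""Tests for track discretisation and (k, beta) inference."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import satwalk as sw
from satwalk import _kernels
from satwalk.discretize import DiscreteTrajectory

from conftest import make_track


class TestDiscretise:
    def test_constant_position_single_site(self):
        t = np.arange(0.0, 10.0, 0.1)
        d = sw.discretise(make_track(t, np.full(t.size, 7.0)), L_ref=20.0)
        assert d.n_hops == 0
        assert d.sites[0] == 0

    def test_uniform_motion_regular_hops(self):
        v, L = 10.0, 20.0
        t = np.arange(0.0, 50.0, 0.1)
        d = sw.discretise(make_track(t, v * t), L_ref=L)
        assert np.all(np.diff(d.sites) == 1)
        # after the first crossing, hops come every L/v hours exactly
        np.testing.assert_allclose(np.diff(d.times[1:]), L / v, rtol=1e-9)

    def test_multisite_frame_jump_split(self):
        # a 3-site jump between two frames becomes 3 unit hops with
        # interpolated, strictly increasing times
        tr = make_track([0.0, 1.0], [0.0, 65.0])
        d = sw.discretise(tr, L_ref=20.0, hysteresis=0.0)
        np.testing.assert_array_equal(d.sites, [0, 1, 2, 3])
        assert np.all(np.diff(d.times) > 0)

    def test_jump_duration_bookkeeping(self, control_dataset):
        tr = control_dataset.tracks[0]
        d = sw.discretise(tr, L_ref=20.0)
        assert d.jump_durations.sum() == pytest.approx(
            d.times[-1] - d.times[0], abs=1e-12)
        assert np.all(d.jump_durations > 0)

    def test_round_trip_recovers_lattice_path(self):
        """Zero noise: discretise(render(path)) == the generating path."""
        model = sw.PopulationModel(noise_sigma_um=0.0)
        for seed in (1, 2, 3):
            sites = sw.simulate_psatw_1d(
                sw.WalkParams(k=1.0, beta=-2.0), 300, seed=seed).sites
            tr = sw.render_continuous_track(sites, 20.0, model, seed=seed + 50,
                                            include_hop_frames=True,
                                            noise_sigma_um=0.0)
            d = sw.discretise(tr, L_ref=20.0)
            np.testing.assert_array_equal(d.sites, sites)

    def test_invalid_params(self):
        tr = make_track([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(sw.ParameterError):
            sw.discretise(tr, L_ref=0.0)
        with pytest.raises(sw.ParameterError):
            sw.discretise(tr, L_ref=20.0, hysteresis=0.6)


class TestClassification:
    def test_monotone_path_all_edge_no_reversals(self):
        d = DiscreteTrajectory(cell_id="m", sites=np.arange(10),
                               times=np.arange(10.0), L_ref=1.0)
        p = sw.classify_and_count(d)
        assert p.n_interior == 0
        assert p.n_edge == 8
        assert p.n_rev_edge == 0

    def test_two_site_bounce_reverses_always(self):
        sites = np.array([0, 1] * 6)[:11]
        d = DiscreteTrajectory(cell_id="b", sites=sites,
                               times=np.arange(11.0), L_ref=1.0)
        p = sw.classify_and_count(d)
        assert p.p_re_hat == 1.0
        assert p.n_rev_edge == p.n_edge == 9

    def test_too_short(self):
        d = DiscreteTrajectory(cell_id="s", sites=np.array([0, 1]),
                               times=np.array([0.0, 1.0]), L_ref=1.0)
        with pytest.raises(sw.InsufficientDataError):
            sw.classify_and_count(d)

    def test_frequencies_converge_to_model_probabilities(self):
        """Law of large numbers: empirical reversal frequencies on a long
        simulated path approach the generating p_ri(k), p_re(k, beta)."""
        k, beta = 1.0, -2.0
        sites = _kernels.psatw_paths_1d(k, beta, 200_000,
                                        np.array([5], np.int64),
                                        np.zeros(1, np.int64))[0]
        d = DiscreteTrajectory(cell_id="x", sites=sites,
                               times=np.arange(sites.size, dtype=float),
                               L_ref=1.0)
        p = sw.classify_and_count(d)
        assert p.p_ri_hat == pytest.approx(sw.reversal_prob_interior(k), abs=0.01)
        assert p.p_re_hat == pytest.approx(sw.reversal_prob_edge(k, beta), abs=0.04)


class TestInversion:
    def test_symmetric_point(self):
        assert sw.invert_params(0.5, 0.5) == (0.0, 0.0)

    def test_round_trip_single(self):
        k, beta = sw.invert_params(sw.reversal_prob_interior(1.0),
                                   sw.reversal_prob_edge(1.0, -1.0))
        assert k == pytest.approx(1.0, abs=1e-12)
        assert beta == pytest.approx(-1.0, abs=1e-12)

    @given(st.floats(0.0, 2.0), st.floats(-3.0, 0.0))
    def test_round_trip_grid(self, k, beta):
        k2, b2 = sw.invert_params(sw.reversal_prob_interior(k),
                                  sw.reversal_prob_edge(k, beta))
        assert abs(k2 - k) < 1e-12
        assert abs(b2 - beta) < 1e-12

    @pytest.mark.parametrize("p_ri, p_re", [(0.0, 0.5), (0.5, 1.0), (1.0, 0.0)])
    def test_degenerate_rejected(self, p_ri, p_re):
        with pytest.raises(sw.ParameterError):
            sw.invert_params(p_ri, p_re)

    def test_pseudocount_fallback_flagged(self):
        # one interior step with zero reversals -> degenerate p_ri regularised
        d = DiscreteTrajectory(cell_id="m",
                               sites=np.array([0, 1, 0, -1, 0, 1]),
                               times=np.arange(6.0), L_ref=1.0)
        p = sw.estimate_params(d)
        assert any(f.startswith("pseudocount") for f in p.flags)
        assert np.isfinite(p.k_hat) and np.isfinite(p.beta_hat)


class TestLref:
    def test_constant_length(self):
        t = np.arange(0.0, 5.0, 0.5)
        assert sw.choose_Lref(make_track(t, t, length=20.0)) == 20.0

    def test_alternating_length_median(self):
        t = np.arange(0.0, 5.0, 0.5)
        length = np.where(np.arange(t.size) % 2 == 0, 18.0, 22.0)
        assert sw.choose_Lref(make_track(t, t, length=length)) == 20.0

    def test_requires_edges(self):
        with pytest.raises(sw.ValidationError):
            sw.choose_Lref(make_track([0.0, 1.0], [0.0, 1.0]))

    def test_recovers_generating_scale(self, control_dataset):
        for tr, (_, row) in zip(control_dataset.tracks,
                                control_dataset.truth.iterrows()):
            assert sw.choose_Lref(tr) == pytest.approx(row.L_ref, rel=0.2)


class TestPopulationFit:
    def test_table_columns_and_flags(self, control_dataset):
        table = sw.fit_population(control_dataset.tracks)
        assert {"cell_id", "L_ref", "p_ri_hat", "p_re_hat", "k_hat",
                "beta_hat", "flags"} <= set(table.columns)
        assert len(table) == len(control_dataset.tracks)

    def test_scatter_centred_on_truth(self):
        """Per-cell estimates are centred on the generating parameters and
        tighten with track length (150 vs 1500 hops)."""
        meds = {}
        for n_hops in (150, 1500):
            ds = sw.generate_dataset("control", 60, n_hops=n_hops, seed=11)
            m = ds.truth.merge(sw.fit_population(ds.tracks), on="cell_id")
            assert abs(np.nanmedian(m.k_hat - m.k)) < 0.1
            assert abs(np.nanmedian(m.beta_hat - m.beta)) < 0.25
            meds[n_hops] = (np.nanmedian(np.abs(m.k_hat - m.k)),
                            np.nanmedian(np.abs(m.beta_hat - m.beta)))
        assert meds[1500][0] < meds[150][0]
        assert meds[1500][1] < meds[150][1]
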