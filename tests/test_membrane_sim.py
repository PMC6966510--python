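"""Generator statistics: confinement, free-diffusion limits, imaging
forward model, internalization kinematics, phantoms."""

import numpy as np
import pytest
from scipy import stats

from tred.membrane_sim import (
    CorralParams,
    ImageStack,
    OpticsParams,
    Trajectory2D,
    WoundSimParams,
    ZStackParams,
    render_movie,
    simulate_corral_ensemble,
    simulate_corral_trajectory,
    simulate_internalization,
    synth_actin_zstack,
    synth_wound_series,
    wound_closure_fraction,
)


class TestCorralSimulator:
    def test_hard_corral_never_leaves_compartment(self):
        p = CorralParams(D_micro=0.05, L_comp=132.1, p_hop=0.0,
                         sigma_loc=0.0, n_steps=500, seed=11)
        tr = simulate_corral_trajectory(p)
        L_um = 132.1 / 1000.0
        assert tr.x.max() - tr.x.min() <= L_um
        assert tr.y.max() - tr.y.min() <= L_um

    def test_free_single_lag_matches_4Ddt(self):
        # ensemble mean squared displacement over one frame = 4 D dt
        D, dt = 0.01, 0.05
        p = CorralParams(D_micro=D, L_comp=np.inf, dt=dt, n_steps=2,
                         sigma_loc=0.0)
        trajs = simulate_corral_ensemble(p, 10_000, seed=1)
        sq = np.array([(tr.x[1] - tr.x[0]) ** 2 + (tr.y[1] - tr.y[0]) ** 2
                       for tr in trajs])
        se = sq.std(ddof=1) / np.sqrt(len(sq))
        assert abs(sq.mean() - 4 * D * dt) < 3 * se

    def test_hard_corral_plateau_is_L2_over_3(self):
        # long-lag ensemble MSD of a square corral -> L^2/3
        L = 132.1
        p = CorralParams(D_micro=0.0177, L_comp=L, p_hop=0.0, sigma_loc=0.0,
                         n_steps=80, seed=2)
        trajs = simulate_corral_ensemble(p, 10_000, seed=2)
        x = np.array([tr.x for tr in trajs])
        y = np.array([tr.y for tr in trajs])
        lag = 60  # >> relaxation time
        msd = np.mean((x[:, lag:] - x[:, :-lag]) ** 2
                      + (y[:, lag:] - y[:, :-lag]) ** 2)
        plateau = (L / 1000.0) ** 2 / 3.0
        assert msd == pytest.approx(plateau, rel=0.05)

    def test_p_hop_one_is_free_diffusion(self):
        # lag-1 displacement distributions indistinguishable (KS)
        kw = dict(D_micro=0.01, dt=0.05, n_steps=2, sigma_loc=0.0)
        hop = simulate_corral_ensemble(
            CorralParams(L_comp=100.0, p_hop=1.0, **kw), 10_000, seed=3)
        free = simulate_corral_ensemble(
            CorralParams(L_comp=np.inf, **kw), 10_000, seed=4)
        dx_hop = np.array([tr.x[1] - tr.x[0] for tr in hop])
        dx_free = np.array([tr.x[1] - tr.x[0] for tr in free])
        assert stats.ks_2samp(dx_hop, dx_free).pvalue > 0.01

    def test_fixed_seed_bit_identical(self):
        p = CorralParams(D_micro=0.01, L_comp=120.0, p_hop=0.1, seed=7,
                         n_steps=100)
        a = simulate_corral_trajectory(p)
        b = simulate_corral_trajectory(p)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    @pytest.mark.parametrize("bad", [
        dict(D_micro=-1.0), dict(L_comp=0.0), dict(p_hop=1.5),
        dict(dt=0.0), dict(n_steps=1), dict(sigma_loc=-1.0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            CorralParams(**{"D_micro": 0.01, **bad})


class TestRenderMovie:
    def test_empty_scene_is_background_only(self):
        opt = OpticsParams(background=0.0, noise_model=False)
        mv = render_movie([], opt)
        assert mv.data.size == 0 or np.all(mv.data == 0)

    def test_static_spot_integrated_signal(self):
        opt = OpticsParams(photons_per_spot=1000.0, background=5.0,
                           noise_model=False, frame_shape=(32, 32))
        x = np.full(5, 16 * 0.107)
        tr = Trajectory2D(0, np.arange(5), np.arange(5) * 0.05, x, x)
        mv = render_movie([tr], opt)
        signal = mv.data[0].sum() - 5.0 * 32 * 32
        assert signal == pytest.approx(1000.0, rel=0.01)

    def test_static_spot_centroid(self):
        opt = OpticsParams(photons_per_spot=1000.0, background=0.0,
                           noise_model=False, frame_shape=(32, 32))
        x0, y0 = 14.3, 17.7  # px
        px_um = 0.107
        tr = Trajectory2D(0, np.arange(2), np.arange(2) * 0.05,
                          np.full(2, x0 * px_um), np.full(2, y0 * px_um))
        mv = render_movie([tr], opt)
        yy, xx = np.mgrid[0:32, 0:32]
        w = mv.data[0]
        assert (w * xx).sum() / w.sum() == pytest.approx(x0, abs=0.05)
        assert (w * yy).sum() / w.sum() == pytest.approx(y0, abs=0.05)

    def test_out_of_frame_warns(self):
        opt = OpticsParams(frame_shape=(16, 16), noise_model=False)
        tr = Trajectory2D(0, np.arange(2), np.arange(2) * 0.05,
                          np.array([5.0, 5.0]), np.array([0.5, 0.5]))
        with pytest.warns(UserWarning, match="field of view"):
            render_movie([tr], opt)


class TestInternalizationSim:
    def test_pure_drift_is_exact(self):
        tr = simulate_internalization(D_mem=0.0, v_in=0.021, t_switch=0.0,
                                      duration=100.0, dt=0.1, sigma_loc=0.0,
                                      axial_jitter_nm=0.0, D_transport=0.0,
                                      seed=0)
        np.testing.assert_allclose(tr.z - tr.z_mem, 0.021 * tr.t, atol=1e-12)

    def test_no_drift_mean_final_z_near_zero(self):
        finals = [simulate_internalization(
            D_mem=0.005, v_in=0.0, t_switch=0.0, duration=60.0, dt=0.1,
            sigma_loc=20.0, seed=s).z[-1] for s in range(100)]
        finals = np.asarray(finals)
        se = finals.std(ddof=1) / 10.0
        assert abs(finals.mean()) < 3 * se

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_internalization(0.01, 0.02, 5.0, duration=-1.0)
        with pytest.raises(ValueError):
            simulate_internalization(0.01, 0.02, t_switch=20.0, duration=10.0)


class TestActinPhantom:
    def test_ground_truth_surface_inside_stack(self):
        st = synth_actin_zstack(ZStackParams(seed=0))
        nz = st.data.shape[0]
        zmax = np.nanmax(st.apical_z_um)
        assert 0 < zmax <= nz * st.voxel_um[0]

    def test_seeded_determinism(self):
        p = ZStackParams(noise_sd=50.0, seed=5)
        assert np.array_equal(synth_actin_zstack(p).data,
                              synth_actin_zstack(p).data)


class TestWoundSeries:
    def test_baseline_wound_empty(self):
        s = synth_wound_series(WoundSimParams(seed=1))
        assert not s.masks[0][s.wound_region].any()

    def test_closure_curve_saturates(self):
        f = wound_closure_fraction(np.array([0.0, 1e6]), 0.05)
        assert f[0] == 0.0 and f[1] == pytest.approx(1.0)

    def test_wound_density_tracks_analytic_curve(self):
        s = synth_wound_series(WoundSimParams(seed=4))
        dens = s.masks[:, s.wound_region].mean(axis=1)
        expected = WoundSimParams().outside_density * s.closure_fraction
        np.testing.assert_allclose(dens, expected, atol=0.03)
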