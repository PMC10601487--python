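"""Wigner sampling, closed-form dynamical limits, representation
equivalence, and reaction-coordinate observables."""

import numpy as np
import pytest

from mrckit import (
    ElectronicParams,
    PhaseSpaceState,
    ReorgMatrix,
    SimConfig,
    build_msh,
    debye_density,
    discretize,
    embed_polyhedron,
    equivalence_report,
    msh_to_mrc,
    propagate,
    random_msh_fixture,
    rc_trajectory_average,
    sample_wigner,
    sqc_propagate,
)
from mrckit.dynamics import _sample_sqc_mapping, _sqc_window_counts, matching_digits
from mrckit.exceptions import InvalidInputError
from mrckit.units import FS_TO_AU_TIME, beta_from_temperature


def _flat_model(F=2, N=4, gamma=0.0, eps=None, er_scale=0.0):
    """Model with controllable reorganization and couplings."""
    if er_scale == 0.0:
        vals = np.zeros((F, F))
    else:
        pts = er_scale * np.eye(F, F - 1)
        diff = pts[:, None] - pts[None, :]
        vals = np.einsum("xyk,xyk->xy", diff, diff)
    er = ReorgMatrix(values=vals)
    gam = gamma * (np.ones((F, F)) - np.eye(F))
    el = ElectronicParams(
        epsilons=np.zeros(F) if eps is None else np.asarray(eps), gammas=gam
    )
    bath = discretize(debye_density(er=0.005, omega_c=0.001), N, er_total=0.005, omega_max=0.006)
    return build_msh(bath, embed_polyhedron(er), el)


class TestWignerSampling:
    def test_moments_match_coth_law(self):
        """beta=1, omega=1: position variance coth(1/2)/2, momentum
        variance coth(1/2)/2, within 3 standard errors at n=1e5."""
        from mrckit.spectral import DiscretizedBath
        from mrckit.msh import PolyhedronVertices

        bath = DiscretizedBath(omegas=np.array([1.0]), er=1.0)
        model = build_msh(
            bath,
            PolyhedronVertices(coords=np.zeros((2, 1))),
            ElectronicParams(epsilons=np.zeros(2), gammas=np.zeros((2, 2))),
        )
        kb = 3.166811563e-6
        T = 1.0 / kb  # beta = 1 in a.u.
        n = 10**5
        states = sample_wigner(model, 0, T, n, seed=0)
        R = np.array([s.positions[0, 0] for s in states])
        var_expect = 0.5 / np.tanh(0.5)
        se = var_expect * np.sqrt(2.0 / n)
        assert abs(np.var(R) - var_expect) < 3 * se
        P = np.array([s.momenta[0, 0] for s in states])
        assert abs(np.var(P) - var_expect) < 3 * se

    def test_high_temperature_classical_limit(self):
        """Sampled position variance approaches k_B T / omega^2 when
        beta*omega << 1."""
        model = _flat_model(N=1)
        w = model.bath.omegas[0]
        T = 3000.0
        beta = beta_from_temperature(T)
        assert beta * w < 0.2
        states = sample_wigner(model, 0, T, 20000, seed=1)
        R = np.array([s.positions[0, 0] for s in states])
        assert np.var(R) == pytest.approx(1.0 / (beta * w**2), rel=0.05)

    def test_mean_potential_at_state_center(self, triad_small):
        """Sample mean of V_X - eps_X matches the harmonic Wigner average
        sum_j omega_j coth(beta omega_j/2)/4 over all (F-1)*N modes."""
        T, n, X = 300.0, 4000, 1
        beta = beta_from_temperature(T)
        states = sample_wigner(triad_small, X, T, n, seed=2)
        vals = np.array(
            [triad_small.potential(X, s.positions) for s in states]
        ) - triad_small.electronic.epsilons[X]
        w = triad_small.mode_frequencies()
        expect = np.sum(w / np.tanh(0.5 * beta * w) / 4.0)
        assert np.mean(vals) == pytest.approx(expect, rel=0.05)

    def test_unknown_center_state_rejected(self, triad_small):
        with pytest.raises(InvalidInputError):
            sample_wigner(triad_small, 9, 300.0, 1, seed=0)

    def test_mrc_target_sampling_maps_from_normal_modes(self, random4, random4_mrc):
        a = sample_wigner(random4, 0, 300.0, 3, seed=5)
        b = sample_wigner(random4_mrc, 0, 300.0, 3, seed=5)
        from mrckit import coords_msh_to_mrc

        for sa, sb in zip(a, b):
            assert sb.basis == "primary_secondary"
            np.testing.assert_allclose(
                coords_msh_to_mrc(random4_mrc, sa.positions), sb.positions, atol=1e-13
            )


class TestClosedFormLimits:
    def test_zero_coupling_populations_constant_mf(self):
        model = _flat_model(F=3, gamma=0.0, er_scale=0.05)
        cfg = SimConfig(method="mf", dt_fs=0.2, t_final_fs=40.0, n_traj=4, seed=0, init_electronic=1)
        trace = propagate(model, None, cfg)
        np.testing.assert_allclose(trace.populations[:, 1], 1.0, atol=1e-12)
        np.testing.assert_allclose(trace.populations[:, 0], 0.0, atol=1e-12)

    def test_zero_coupling_sqc_stays_in_initial_window(self):
        model = _flat_model(F=2, gamma=0.0, er_scale=0.05)
        cfg = SimConfig(method="sqc", dt_fs=0.2, t_final_fs=20.0, n_traj=32, seed=0)
        trace = sqc_propagate(model, None, cfg)
        np.testing.assert_allclose(trace.populations[:, 0], 1.0, atol=1e-12)

    def test_rabi_oscillation_closed_form(self):
        """Two degenerate uncoupled-bath states with constant Gamma:
        sigma_11(t) = cos^2(Gamma t) to 1e-6 at dt = 0.01 fs."""
        gamma = 0.002
        model = _flat_model(F=2, gamma=gamma, er_scale=0.0)
        cfg = SimConfig(method="mf", dt_fs=0.01, t_final_fs=10.0, n_traj=1, seed=0)
        trace = propagate(model, None, cfg)
        t_au = trace.times * FS_TO_AU_TIME
        expect = np.cos(gamma * t_au) ** 2
        assert np.max(np.abs(trace.populations[:, 0] - expect)) < 1e-6

    def test_nuclear_only_limit_matches_analytic_harmonic_motion(self):
        """Gamma = 0: nuclei follow exact classical harmonic motion on the
        initial surface; velocity-Verlet at a resolved time step matches
        the analytic normal-mode solution to 1e-8."""
        model = _flat_model(F=2, gamma=0.0, er_scale=0.1, N=4)
        rng = np.random.default_rng(3)
        R0 = model.state_minimum(0) + 0.3 * rng.standard_normal(model.nuclear_shape)
        P0 = 1e-3 * rng.standard_normal(model.nuclear_shape)
        st = PhaseSpaceState(R0.copy(), P0.copy(), "normal_mode")
        cfg = SimConfig(method="mf", dt_fs=0.001, t_final_fs=0.1, n_traj=1, seed=0)
        _, (R, P, _) = propagate(model, [st], cfg, return_final=True)
        w = model.mode_frequencies()
        t = 0.1 * FS_TO_AU_TIME
        Rmin = model.state_minimum(0)
        R_exact = Rmin + (R0 - Rmin) * np.cos(w * t) + P0 * np.sin(w * t) / w
        P_exact = -(R0 - Rmin) * w * np.sin(w * t) + P0 * np.cos(w * t)
        assert np.max(np.abs(R[0] - R_exact)) < 1e-8
        assert np.max(np.abs(P[0] - P_exact)) < 1e-8


class TestSQCEstimator:
    def test_initial_sampling_lands_in_occupied_window(self):
        rng = np.random.default_rng(0)
        for m in (0, 2):
            c = _sample_sqc_mapping(rng, 4, m, 1.0 / 3.0)
            counts = _sqc_window_counts(np.abs(c[None, :]) ** 2, 1.0 / 3.0)
            assert counts[0, m] == 1.0
            assert counts.sum() == 1.0

    def test_window_counts_reject_ambiguous_points(self):
        # all actions below 1: no window claims the trajectory
        pops = np.array([[0.5, 0.4, 0.4]]) + 1.0 / 3.0
        assert _sqc_window_counts(pops, 1.0 / 3.0).sum() == 0.0

    def test_ensemble_convergence_jackknife(self):
        """Doubling the trajectory count leaves the population curves
        within each other's jackknife error bands (scaled-down ensembles)."""
        model = _flat_model(F=3, gamma=0.001, er_scale=0.03, N=8)
        curves = {}
        errs = {}
        for n in (1000, 2000):
            cfg = SimConfig(
                method="sqc", dt_fs=0.5, t_final_fs=100.0, n_traj=n, seed=7, output_stride=20
            )
            trace, raw = propagate(model, None, cfg, _return_raw=True)
            curves[n] = trace.populations[:, 0]
            # jackknife over 10 blocks of the binned estimator
            blocks = np.array_split(np.arange(n), 10)
            from mrckit.dynamics import _sqc_window_counts as wc

            est = []
            for drop in range(10):
                keep = np.concatenate([blocks[i] for i in range(10) if i != drop])
                cnt = np.stack(
                    [wc(raw[keep, i], 1.0 / 3.0).sum(axis=0) for i in range(raw.shape[1])]
                )
                est.append(cnt[:, 0] / cnt.sum(axis=1))
            est = np.array(est)
            errs[n] = 3.0 * np.sqrt(9.0) * np.std(est, axis=0)
        band = errs[1000] + errs[2000] + 1e-3
        assert np.all(np.abs(curves[1000] - curves[2000]) <= band)


class TestEquivalence:
    def test_matching_digits_metric(self):
        assert matching_digits([0.5, 0.5], [0.5, 0.5]) == 16
        assert matching_digits([0.5], [0.5 + 1e-8]) in (7, 8)
        assert matching_digits([1.0], [2.0]) == 0

    def test_short_time_equivalence_all_methods(self, random4, random4_mrc):
        for method in ("mf", "sqc"):
            cfg = SimConfig(method=method, dt_fs=0.1, t_final_fs=2.0, n_traj=2, seed=3, init_nuclear=3)
            rep = equivalence_report(random4, random4_mrc, cfg)
            assert rep.digits.min() >= 11

    def test_agreement_does_not_degrade_with_smaller_step(self, random4, random4_mrc):
        mins = []
        for dt in (0.1, 0.05):
            cfg = SimConfig(method="mf", dt_fs=dt, t_final_fs=2.0, n_traj=1, seed=3)
            rep = equivalence_report(random4, random4_mrc, cfg)
            mins.append(rep.digits.min())
        assert mins[1] >= mins[0] - 1

    def test_basis_tag_mismatch_rejected(self, random4, random4_mrc):
        st = sample_wigner(random4, 0, 300.0, 1, seed=0)
        cfg = SimConfig(method="mf", dt_fs=0.1, t_final_fs=1.0)
        with pytest.raises(InvalidInputError, match="basis"):
            propagate(random4_mrc, st, cfg)


class TestReactionCoordinateObservables:
    def test_zero_reorg_rc_stays_at_origin(self):
        model = _flat_model(F=2, gamma=0.0, er_scale=0.0, N=4)
        mrc = msh_to_mrc(model)
        n = 64
        cfg = SimConfig(method="mf", dt_fs=0.2, t_final_fs=20.0, n_traj=n, seed=0)
        trace = propagate(mrc, None, cfg)
        # equilibrium ensemble about y=0: the mean stays at 0 within the
        # coth-law thermal spread of y over sqrt(n)
        beta = beta_from_temperature(cfg.temperature)
        w = model.bath.omegas
        T = mrc.basis_matrix
        var_y = np.sum(T[:, 0] ** 2 / np.tanh(0.5 * beta * w) / (2.0 * w))
        assert np.max(np.abs(trace.rc_mean)) < 5.0 * np.sqrt(var_y / n)

    def test_displaced_start_oscillates_near_primary_frequency(self):
        """Weakly damped two-state reaction-coordinate model started away
        from the minimum with Gamma=0: y(t) oscillates about the
        initial-state minimum at a frequency near Omega (classical
        harmonic-oscillator oracle)."""
        from mrckit.mrc import build_goa_model
        from mrckit.spectral import ohmic_density

        Omega = 0.002
        sec = discretize(ohmic_density(eta=1e-4, omega_c=0.004), 32, er_total=2e-7)
        mrc = build_goa_model(Omega, sec, er=0.01)
        w0 = np.zeros(mrc.nuclear_shape)
        w0[0, 0] = 0.5 * abs(mrc.primary_shifts[1, 0])  # midway toward state 2
        st = PhaseSpaceState(w0, np.zeros_like(w0), "primary_secondary")
        cfg = SimConfig(method="mf", dt_fs=0.5, t_final_fs=2000.0, n_traj=1, seed=0)
        trace = propagate(mrc, [st], cfg)
        y = trace.rc_mean[:, 0]
        assert abs(np.mean(y)) < 0.2 * w0[0, 0]  # oscillates about y_min = 0
        yc = y - np.mean(y)
        freqs = np.fft.rfftfreq(yc.size, d=cfg.dt_fs * FS_TO_AU_TIME) * 2 * np.pi
        peak = freqs[np.argmax(np.abs(np.fft.rfft(yc))[1:]) + 1]
        assert peak == pytest.approx(Omega, rel=0.05)

    def test_rc_average_weighting(self, random4, random4_mrc):
        cfg1 = SimConfig(method="mf", dt_fs=0.2, t_final_fs=4.0, n_traj=2, seed=0, init_nuclear=3)
        cfg2 = SimConfig(method="mf", dt_fs=0.2, t_final_fs=4.0, n_traj=4, seed=1, init_nuclear=3)
        t1 = propagate(random4_mrc, None, cfg1)
        t2 = propagate(random4_mrc, None, cfg2)
        avg = rc_trajectory_average([t1, t2])
        np.testing.assert_allclose(avg, (2 * t1.rc_mean + 4 * t2.rc_mean) / 6.0)

    def test_msh_runs_have_no_rc_series(self, random4):
        cfg = SimConfig(method="mf", dt_fs=0.2, t_final_fs=2.0, n_traj=1, seed=0, init_nuclear=3)
        trace = propagate(random4, None, cfg)
        assert trace.rc_mean is None
        with pytest.raises(InvalidInputError):
            rc_trajectory_average(trace)

    def test_variance_of_mean_scales_inversely_with_ensemble(self):
        model = _flat_model(F=2, gamma=0.0, er_scale=0.0, N=4)
        mrc = msh_to_mrc(model)
        spreads = []
        for n in (16, 256):
            cfg = SimConfig(method="mf", dt_fs=0.5, t_final_fs=200.0, n_traj=n, seed=5)
            spreads.append(np.std(propagate(mrc, None, cfg).rc_mean[:, 0]))
        assert spreads[1] < 0.5 * spreads[0]
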