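import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

import shbdecay as sd
from shbdecay.constants import AMU_A2_FS2_TO_EV, KB_EV_K
from shbdecay.errors import ConfigurationError, ParameterError
from shbdecay.model_system import Restraint

KT300 = KB_EV_K * 300.0


class TestBuildSurface:
    @pytest.mark.parametrize("hb", [2.0, 5.5])
    def test_hb_length_out_of_range(self, hb):
        with pytest.raises(ParameterError):
            sd.build_surface(hb)

    @pytest.mark.parametrize("c", [0.0, -0.1])
    def test_nonpositive_coupling_rejected(self, c):
        with pytest.raises(ParameterError):
            sd.build_surface(2.5, sd.SurfaceParams(coupling=c))

    def test_shb_barrier_at_most_thermal(self, shb_surface):
        assert shb_surface.ground_barrier() <= KT300 + 1e-12

    def test_barrier_strictly_increases_with_hb_length(self):
        barriers = [sd.build_surface(hb).ground_barrier()
                    for hb in (2.5, 3.0, 3.5, 4.5)]
        assert all(a < b for a, b in zip(barriers, barriers[1:]))

    def test_min_excited_gap_decreases_with_hb_length(self):
        gaps = [sd.build_surface(hb).min_excited_gap()
                for hb in (2.5, 3.0, 3.5, 4.5)]
        assert all(a > b for a, b in zip(gaps, gaps[1:]))

    def test_gap_bounded_below_by_twice_coupling(self, shb_surface):
        d = np.linspace(-1, 1, 41)
        q = np.linspace(-2, 4, 41)
        dd, qq = np.meshgrid(d, q)
        gap = shb_surface.gap(dd.ravel(), qq.ravel())
        assert np.all(gap >= 2 * shb_surface.coupling - 1e-12)

    def test_gap_equals_two_c_at_diabat_degeneracy(self):
        # the diabats cross along q on the long-bond surface; at the
        # crossing the adiabatic gap must be exactly 2c
        surf = sd.build_surface(4.5, sd.SurfaceParams(coupling=0.05))
        dv = lambda q: float(surf.diabat_1(0.0, q) - surf.diabat_2(0.0, q))
        q_cross = brentq(dv, 0.0, 5.0)
        assert surf.gap(0.0, q_cross) == pytest.approx(0.10, abs=1e-12)


class TestGroundSampling:
    def test_equipartition_long_run(self, shb_surface):
        traj = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 100_000,
                                           seed=3)
        ke = 0.5 * np.sum(shb_surface.masses * traj.velocities**2,
                          axis=1) * AMU_A2_FS2_TO_EV
        per_dof = ke[1000:].mean() / 2.0
        assert per_dof == pytest.approx(KT300 / 2.0, rel=0.05)

    def test_kinetic_energy_distribution_is_canonical(self, shb_surface):
        # 2 DOF -> kinetic energy is chi^2_2, i.e. exponential with mean kT
        traj = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 601_000,
                                           seed=8, tau=5.0)
        ke = 0.5 * np.sum(shb_surface.masses * traj.velocities**2,
                          axis=1) * AMU_A2_FS2_TO_EV
        samples = ke[1000::60][:10_000]
        assert len(samples) == 10_000
        p = stats.kstest(samples, "expon", args=(0.0, KT300)).pvalue
        assert p > 0.01

    def test_flat_potential_zero_velocity_is_static(self):
        # every force term off: both diabats globally constant
        params = sd.SurfaceParams(barrier_shb=0.0, barrier_saturation=0.0,
                                  k_ground_q=0.0, k_excited_delta=0.0,
                                  gap_slope=0.0, stiffening_shb=0.0)
        surf = sd.build_surface(2.5, params)
        traj = sd.sample_ground_trajectory(
            surf, 300.0, 0.5, 200, seed=0, thermostat=None,
            init_coords=[0.3, 0.0], init_velocities=[0.0, 0.0])
        assert np.allclose(traj.coords, traj.coords[0])

    def test_harmonic_mode_boltzmann_variance(self, shb_surface):
        # the q mode is separable and harmonic on the ground diabat:
        # position marginal must be Gaussian with variance kT/k
        traj = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 100_000,
                                           seed=5)
        q = traj.coords[5000:, 1]
        expected = KT300 / shb_surface.params.k_ground_q
        assert q.var() == pytest.approx(expected, rel=0.10)

    def test_deterministic_under_fixed_seed(self, shb_surface):
        a = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 500, seed=7)
        b = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 500, seed=7)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.sigma, b.sigma)

    def test_restrained_coordinate_stays_near_target(self, shb_surface):
        r = Restraint("q", 0.3, force_constant=30.0)
        traj = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 40_000,
                                           seed=3, restraints=(r,))
        q = traj.coords[2000:, 1]
        assert abs(q.mean() - 0.3) < q.std()

    def test_unknown_restraint_coordinate(self, shb_surface):
        with pytest.raises(ConfigurationError):
            sd.sample_ground_trajectory(
                shb_surface, 300.0, 0.5, 10, seed=0,
                restraints=(Restraint("bogus", 0.0),))

    def test_invariants_of_frames(self, shb_surface):
        traj = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 2000, seed=2)
        assert np.all(np.diff(traj.times) > 0)
        assert np.allclose(np.diff(traj.times), traj.dt)
        assert np.all(traj.e_s1 >= traj.e_s0)


class TestExcitedTrajectory:
    def test_frame_count_one_ps(self, shb_surface):
        g = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 100, seed=1)
        ex = sd.run_excited_trajectory(shb_surface, g.frame(-1), 1000.0, 0.5,
                                       seed=2)
        assert len(ex) == 2001
        assert ex.active_state == "S1"

    def test_non_integral_duration_rejected(self, shb_surface):
        g = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 10, seed=1)
        with pytest.raises(ConfigurationError):
            sd.run_excited_trajectory(shb_surface, g.frame(-1), 10.3, 0.5)

    def test_sigma_tiny_on_huge_gap_surface(self, shb_surface):
        g = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 2000, seed=4)
        near = sd.run_excited_trajectory(sd.build_surface(4.5), g.frame(-1),
                                         500.0, 0.5, seed=5)
        far_params = sd.SurfaceParams(coupling=2.0, vertical_gap=30.0)
        far = sd.run_excited_trajectory(sd.build_surface(2.5, far_params),
                                        g.frame(-1), 500.0, 0.5, seed=5)
        assert np.max(np.abs(far.sigma)) < 1e-3 * np.max(np.abs(near.sigma))


class TestAnalyticNac:
    def test_zero_for_frozen_nuclei(self, shb_surface):
        frame = {"coords": np.array([0.2, 0.4]),
                 "velocities": np.zeros(2)}
        assert sd.analytic_nac(shb_surface, frame) == 0.0

    def test_linear_in_velocity(self, shb_surface):
        frame = {"coords": np.array([0.1, 0.5]),
                 "velocities": np.array([0.01, -0.02])}
        doubled = dict(frame, velocities=2 * frame["velocities"])
        assert sd.analytic_nac(shb_surface, doubled) == pytest.approx(
            2 * sd.analytic_nac(shb_surface, frame))

    def test_matches_wavefunction_overlap_finite_difference(self, shb_surface):
        # independent estimate: sigma ~ <phi0(t)|phi1(t+dt)>/dt, where the
        # adiabatic states are (cos th, sin th) / (-sin th, cos th), so the
        # overlap is sin(th(t+dt) - th(t))
        traj = sd.sample_ground_trajectory(shb_surface, 300.0, 0.5, 2000, seed=9)
        dt_fd = 0.05
        for i in (100, 500, 900, 1500):
            fr = traj.frame(i)
            analytic = sd.analytic_nac(shb_surface, fr)
            ahead = fr["coords"] + fr["velocities"] * dt_fd
            th0 = shb_surface.mixing_angle(*fr["coords"])
            th1 = shb_surface.mixing_angle(*ahead)
            fd = np.sin(th1 - th0) / dt_fd
            assert analytic == pytest.approx(fd, rel=0.01)
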