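import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import shbdecay as sd
from shbdecay.constants import KB_EV_K
from shbdecay.descriptors import Geometry, classify_wells, dihedral_angle
from shbdecay.errors import GeometryError, InputError

KT300 = KB_EV_K * 300.0


def metropolis_samples(potential, n, kt, step=0.15, x0=0.0, seed=0, burn=5000):
    """Independent Boltzmann-sampling oracle for a 1-D potential."""
    rng = np.random.default_rng(seed)
    x, out = x0, np.empty(n + burn)
    v = potential(x)
    for i in range(n + burn):
        xp = x + rng.normal(0.0, step)
        vp = potential(xp)
        if rng.random() < np.exp(-(vp - v) / kt):
            x, v = xp, vp
        out[i] = x
    return out[burn:]


class TestProtonTransferCoordinate:
    def test_equidistant_proton_gives_zero(self):
        coords = np.array([[0, 0, 0], [1.25, 0, 0], [2.5, 0, 0]], float)
        assert sd.proton_transfer_coordinate(coords, 0, 1, 2) == 0.0

    def test_arithmetic_example(self):
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [2.45, 0, 0]], float)
        assert sd.proton_transfer_coordinate(coords, 0, 1, 2) == pytest.approx(-0.45)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_antisymmetric_under_oxygen_exchange(self, seed):
        coords = np.random.default_rng(seed).normal(size=(3, 3))
        a = sd.proton_transfer_coordinate(coords, 0, 1, 2)
        b = sd.proton_transfer_coordinate(coords, 2, 1, 0)
        assert a == pytest.approx(-b, abs=1e-12)

    def test_duplicate_indices_rejected(self):
        coords = np.zeros((3, 3))
        with pytest.raises(InputError):
            sd.proton_transfer_coordinate(coords, 0, 0, 2)


class TestFreeEnergyProfile:
    def test_harmonic_curvature_recovered(self, rng):
        k = 2.0
        x = rng.normal(0.0, np.sqrt(KT300 / k), 100_000)
        prof = sd.free_energy_profile(x, 300.0)
        ok = prof.defined
        coef = np.polyfit(prof.bin_centers[ok], prof.free_energy[ok], 2)
        assert 2 * coef[0] == pytest.approx(k, rel=0.10)
        assert np.nanmin(prof.free_energy) == 0.0

    def test_uniform_samples_give_flat_profile(self, rng):
        n, bins = 200_000, 50
        x = rng.uniform(-1, 1, n)
        prof = sd.free_energy_profile(x, 300.0, bins)
        # drop padding bins and the partially covered boundary bins
        inner = prof.free_energy[3:-3]
        # bin noise: F fluctuation ~ kT / sqrt(count per bin)
        se = KT300 / np.sqrt(n / bins)
        assert np.nanmax(np.abs(inner - np.nanmean(inner))) < 3 * se * np.sqrt(2)

    def test_double_well_metropolis_oracle(self):
        B, d0 = 0.06, 0.35
        b, a = 2 * B / d0**2, B / d0**4
        samples = metropolis_samples(lambda x: a * x**4 - b * x**2, 100_000,
                                     KT300, x0=d0, seed=4)
        prof = sd.free_energy_profile(samples, 300.0)
        assert prof.well_count == 2
        assert prof.barrier == pytest.approx(B, rel=0.15)
        # symmetry within noise
        f = prof.free_energy
        sym = np.abs(f - f[::-1])
        assert np.nanmedian(sym) < 3 * KT300 / np.sqrt(len(samples) / 50)

    def test_estimator_error_shrinks_with_sample_size(self):
        # rms deviation of the recovered profile from the closed form
        # -- averaged over several seeds -- must fall with sample size
        k = 1.5

        def rms_err(n, seed):
            x = np.random.default_rng(seed).normal(0.0, np.sqrt(KT300 / k), n)
            prof = sd.free_energy_profile(x, 300.0)
            ok = prof.defined & (prof.n_samples > 25)
            truth = 0.5 * k * prof.bin_centers[ok] ** 2
            dev = prof.free_energy[ok] - truth
            return np.sqrt(np.mean((dev - dev.mean()) ** 2))

        small = np.mean([rms_err(10_000, s) for s in range(5)])
        large = np.mean([rms_err(100_000, s) for s in range(5)])
        assert large < small

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            sd.free_energy_profile([])

    def test_empty_bins_are_nan_not_zero(self, rng):
        x = np.concatenate([rng.normal(0, 0.05, 5000),
                            rng.normal(3.0, 0.05, 5000)])
        prof = sd.free_energy_profile(x, 300.0)
        gaps = prof.n_samples == 0
        assert gaps.any()
        assert np.all(np.isnan(prof.free_energy[gaps]))


class TestClassifyWells:
    def test_harmonic_profile_is_single(self, rng):
        x = rng.normal(0.0, 0.1, 50_000)
        prof = sd.free_energy_profile(x, 300.0)
        assert classify_wells(prof) == "single"
        assert prof.well_count == 1

    def test_shb_ground_trajectory_is_thermal_double_well(self, shb_ground_long):
        prof = sd.free_energy_profile(shb_ground_long.coords[:, 0], 300.0)
        assert classify_wells(prof) == "double"
        # the designed barrier is ~0.8 kT; the sampled estimate carries a
        # positive max-of-noise bias, so allow up to ~2 kT ("order of kT")
        assert prof.barrier < 2 * KT300

    def test_all_undefined_profile_rejected(self):
        prof = sd.FreeEnergyProfile(
            bin_centers=np.linspace(0, 1, 30),
            free_energy=np.full(30, np.nan), temperature=300.0,
            n_samples=np.zeros(30, dtype=int))
        with pytest.raises(InputError):
            classify_wells(prof)


class TestRingDeplanarization:
    @staticmethod
    def pentagon(lift=0.0):
        ang = 2 * np.pi * np.arange(5) / 5
        coords = np.stack([np.cos(ang), np.sin(ang), np.zeros(5)], axis=1)
        coords[2, 2] += lift
        return coords

    def test_planar_pentagon_is_zero(self):
        assert sd.ring_deplanarization(self.pentagon(), range(5)) == pytest.approx(0.0, abs=1e-9)

    def test_envelope_matches_brute_force_torsions(self):
        coords = self.pentagon(lift=0.5)

        def torsion(p):  # independent evaluation via normal-vector angle
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            cosv = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            return np.degrees(np.arccos(np.clip(cosv, -1, 1)))

        expected = sum(abs(torsion(coords[[(k + m) % 5 for m in range(4)]]))
                       for k in range(5))
        got = sd.ring_deplanarization(coords, range(5))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_invariant_under_rigid_motion(self):
        coords = self.pentagon(lift=0.4)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -2.0, 1.5])
        assert sd.ring_deplanarization(moved, range(5)) == pytest.approx(
            sd.ring_deplanarization(coords, range(5)), abs=1e-9)

    def test_collinear_ring_raises_naming_atoms(self):
        coords = np.zeros((5, 3))
        coords[:, 0] = np.arange(5)  # all on a line
        with pytest.raises(GeometryError) as exc:
            sd.ring_deplanarization(coords, range(5))
        assert exc.value.atoms is not None


class TestBondLengthSeries:
    def test_static_pair_constant_series(self):
        frames = np.zeros((10, 2, 3))
        frames[:, 1, 0] = 1.23
        series, hist, edges = sd.bond_length_series(frames, 0, 1)
        assert np.allclose(series, 1.23)
        assert hist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_histogram_mass_is_one(self, rng):
        frames = rng.normal(size=(500, 3, 3))
        _, hist, _ = sd.bond_length_series(frames, 0, 2)
        assert hist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_long_bond_condition_shifts_co_mode_up(self):
        # excited-state distortion grows when the stiffening is weak:
        # the carbonyl histogram mode moves up by ~0.1 A
        from shbdecay.toy_molecule import CO_BOND, embed_trajectory
        modes = {}
        for hb in (2.5, 4.5):
            surf = sd.build_surface(hb)
            g = sd.sample_ground_trajectory(surf, 300.0, 0.5, 4000, seed=21)
            ex = sd.run_excited_trajectory(surf, g.frame(-1), 1000.0, 0.5,
                                           seed=22)
            cart = embed_trajectory(ex, hb)
            _, hist, edges = sd.bond_length_series(cart, *CO_BOND)
            centers = 0.5 * (edges[:-1] + edges[1:])
            modes[hb] = centers[np.argmax(hist)]
        assert modes[4.5] - modes[2.5] == pytest.approx(0.1, abs=0.05)


class TestHbDistances:
    def test_constructed_shb_pair(self):
        geom = Geometry(("O", "H", "O"),
                        np.array([[0, 0, 0], [1.2, 0, 0], [2.45, 0, 0]], float))
        pairs = sd.hb_distances(geom)
        assert len(pairs) == 1
        (i, j), d, shb = pairs[0]
        assert (i, j) == (0, 2) and d == pytest.approx(2.45) and shb

    def test_far_oxygens_empty(self):
        geom = Geometry(("O", "O"), np.array([[0, 0, 0], [4.0, 0, 0]], float))
        assert sd.hb_distances(geom, cutoff=3.2) == []

    def test_no_heavy_atoms_rejected(self):
        geom = Geometry(("H", "H"), np.zeros((2, 3)))
        with pytest.raises(InputError):
            sd.hb_distances(geom)

    def test_sorted_ascending_and_mixed_elements(self):
        geom = Geometry(("O", "N", "O"),
                        np.array([[0, 0, 0], [2.9, 0, 0], [0, 2.5, 0]], float))
        pairs = sd.hb_distances(geom)
        dists = [d for _, d, _ in pairs]
        assert dists == sorted(dists)
        assert pairs[0][2] and not pairs[1][2]  # 2.5 is SHB, 2.9 is not
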