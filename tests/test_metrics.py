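"""Analysis suite: thickness, strain, order parameter, pressure, smoothing."""
import numpy as np
import pytest
from scipy import stats

from memshock import (density_profile, membrane_thickness,
                      max_compressive_strain, instantaneous_order_parameter,
                      order_parameter_sch, area_per_lipid, mean_pressure,
                      local_pressure_profile, moving_average, response_time,
                      shock_speed, MetricSeries, build_system,
                      default_forcefield)
from memshock.metrics import MetricError, PressureProfile
from memshock.system import (ParticleFrame, Topology, ForceField,
                             ROLE_HEAD, ROLE_TAIL,
                             LEAFLET_PROXIMAL, LEAFLET_DISTAL)
from memshock.units import KB, internal_pressure_to_gpa


def _bare_frame(pos, box=(50.0, 50.0, 100.0), vel=None):
    n = len(pos)
    return ParticleFrame(np.asarray(pos, float),
                         np.zeros((n, 3)) if vel is None else np.asarray(vel),
                         np.full(n, 72.0), np.array(["W"] * n), np.arange(n),
                         np.array(box))


def _director_system(directions, leaflets=None):
    """Two beads per director, vector given by ``directions`` rows."""
    directions = np.asarray(directions, float)
    nd = len(directions)
    pos = np.zeros((2 * nd, 3))
    pos[:, :] = 50.0
    pos[1::2] += directions
    frame = ParticleFrame(pos, np.zeros((2 * nd, 3)), np.full(2 * nd, 72.0),
                          np.array(["T"] * (2 * nd)),
                          np.repeat(np.arange(nd), 2),
                          np.array([200.0, 200.0, 200.0]))
    leaf = leaflets if leaflets is not None else np.zeros(nd, np.int8)
    topo = Topology(
        bead_role=np.full(2 * nd, ROLE_TAIL, np.int8),
        bonds=np.zeros((0, 2), np.int64), bond_r0=[], bond_k=[],
        lipid_id=np.repeat(np.arange(nd), 2),
        leaflet_of_lipid=leaf,
        director_pairs=np.array([[2 * k, 2 * k + 1] for k in range(nd)]),
        director_lipid=np.arange(nd), director_kind="ch",
    )
    return frame, topo


class TestDensityProfile:
    def test_delta_distribution(self):
        frame = _bare_frame([[1.0, 2.0, 50.0]] * 40)
        prof = density_profile(frame, np.arange(40), 1.0)
        occupied = prof.density > 0
        assert occupied.sum() == 1
        assert prof.integral(frame.lateral_area) == pytest.approx(40)

    def test_uniform_counts_poisson(self):
        rng = np.random.default_rng(0)
        n = 10_000
        frame = _bare_frame(np.c_[rng.uniform(0, 50, (n, 2)),
                                  rng.uniform(0, 100, n)])
        prof = density_profile(frame, np.arange(n), 5.0)
        counts = prof.density * frame.lateral_area * prof.bin_width
        lam = n / len(counts)
        assert np.all(np.abs(counts - lam) < 5 * np.sqrt(lam))

    def test_two_gaussian_clouds_two_peaks(self):
        rng = np.random.default_rng(1)
        z = np.concatenate([rng.normal(30, 2, 500), rng.normal(70, 2, 500)])
        frame = _bare_frame(np.c_[rng.uniform(0, 50, (1000, 2)), z])
        prof = density_profile(frame, np.arange(1000), 1.0)
        lower = prof.bin_centers < 50
        peak_lo = prof.bin_centers[lower][np.argmax(prof.density[lower])]
        peak_hi = prof.bin_centers[~lower][np.argmax(prof.density[~lower])]
        assert abs(peak_lo - 30) < 3 and abs(peak_hi - 70) < 3

    def test_empty_selection_rejected(self):
        frame = _bare_frame([[0, 0, 5.0]])
        with pytest.raises(MetricError):
            density_profile(frame, np.array([], int), 1.0)


class TestThickness:
    def _head_system(self, z_lo, z_hi, n_per=200, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        z = np.concatenate([z_lo + sigma * rng.standard_normal(n_per),
                            z_hi + sigma * rng.standard_normal(n_per)])
        pos = np.c_[rng.uniform(0, 50, (2 * n_per, 2)), z]
        frame = _bare_frame(pos)
        topo = Topology(
            bead_role=np.full(2 * n_per, ROLE_HEAD, np.int8),
            bonds=np.zeros((0, 2), np.int64), bond_r0=[], bond_k=[],
            lipid_id=np.arange(2 * n_per),
            leaflet_of_lipid=np.r_[np.zeros(n_per, np.int8),
                                   np.ones(n_per, np.int8)],
            director_pairs=np.zeros((0, 2), np.int64), director_lipid=[],
        )
        return frame, topo

    def test_constructed_separation(self):
        frame, topo = self._head_system(30.00, 70.24)
        assert membrane_thickness(frame, topo) == pytest.approx(40.24, abs=0.02)

    def test_translation_invariance(self):
        frame, topo = self._head_system(30.0, 70.0, sigma=1.5, seed=3)
        t0 = membrane_thickness(frame, topo)
        moved = frame.copy()
        moved.positions[:, 2] += 7.0
        assert membrane_thickness(moved, topo) == pytest.approx(t0, abs=0.3)

    def test_gaussian_leaflets_monte_carlo(self):
        """Monte-Carlo oracle: Gaussian leaflets at 25/65 A, sigma = 2 A."""
        vals = [membrane_thickness(*self._head_system(25.0, 65.0, n_per=500,
                                                      sigma=2.0, seed=s))
                for s in range(100)]
        assert np.mean(vals) == pytest.approx(40.0, abs=0.5)

    def test_single_peak_error(self):
        frame, topo = self._head_system(50.0, 50.0)
        with pytest.raises(MetricError):
            membrane_thickness(frame, topo)


class TestStrain:
    def test_dip_arithmetic(self):
        s = MetricSeries([0, 1, 2], [40.0, 28.0, 40.0], "thickness_A")
        assert max_compressive_strain(s, 40.0) == pytest.approx(0.30)

    def test_constant_series_zero(self):
        s = MetricSeries([0, 1], [40.0, 40.0], "thickness_A")
        assert max_compressive_strain(s, 40.0) == 0.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        vals = 40 + rng.normal(0, 3, 50)
        s = MetricSeries(np.arange(50), vals, "thickness_A")
        brute = max((40 - v) / 40 for v in vals)
        assert max_compressive_strain(s, 40.0) == pytest.approx(brute)

    def test_thickening_gives_negative(self):
        s = MetricSeries([0, 1], [41.0, 42.0], "thickness_A")
        assert max_compressive_strain(s, 40.0) < 0


class TestOrderParameter:
    def test_parallel_directors(self):
        frame, topo = _director_system([[0, 0, 1.0]] * 5)
        assert instantaneous_order_parameter(frame, topo) == pytest.approx(-1.0)

    def test_in_plane_directors(self):
        frame, topo = _director_system([[1.0, 0, 0], [0, 1.0, 0]] * 3)
        assert instantaneous_order_parameter(frame, topo) == pytest.approx(0.5)

    def test_magic_angle_null(self):
        c = 1 / np.sqrt(3)
        s = np.sqrt(1 - c**2)
        frame, topo = _director_system([[s, 0, c]] * 4)
        assert instantaneous_order_parameter(frame, topo) == pytest.approx(
            0.0, abs=1e-12)

    def test_rotation_about_z_invariant(self):
        rng = np.random.default_rng(4)
        d = rng.normal(size=(40, 3))
        frame, topo = _director_system(d)
        s0 = instantaneous_order_parameter(frame, topo)
        for ang in rng.uniform(0, 2 * np.pi, 5):
            R = np.array([[np.cos(ang), -np.sin(ang), 0],
                          [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
            frame_r, topo_r = _director_system(d @ R.T)
            assert instantaneous_order_parameter(frame_r, topo_r) == \
                pytest.approx(s0, abs=1e-10)

    def test_leaflet_filter(self):
        frame, topo = _director_system([[0, 0, 1.0], [1.0, 0, 0]],
                                       leaflets=np.array([0, 1], np.int8))
        assert instantaneous_order_parameter(
            frame, topo, LEAFLET_PROXIMAL) == pytest.approx(-1.0)
        assert instantaneous_order_parameter(
            frame, topo, LEAFLET_DISTAL) == pytest.approx(0.5)

    def test_zero_length_director_excluded(self):
        frame, topo = _director_system([[0, 0, 1.0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="zero-length"):
            val = instantaneous_order_parameter(frame, topo)
        assert val == pytest.approx(-1.0)

    def test_chain_mapping_halves_and_flips(self):
        """CG chain directors along z -> conventional -S_CD = +1/2."""
        frame, topo = _director_system([[0, 0, 1.0]] * 5)
        topo.director_kind = "chain"
        assert order_parameter_sch(frame, topo) == pytest.approx(0.5)


class TestAreaPerLipid:
    def _system(self, per_leaflet, sterols=0):
        n = 2 * per_leaflet
        species = []
        for k in range(n):
            species.append("HC" if k % per_leaflet < sterols else "H")
        frame = ParticleFrame(np.zeros((n, 3)), np.zeros((n, 3)),
                              np.full(n, 72.0), np.array(species),
                              np.arange(n), np.array([109.8, 109.8, 100.0]))
        topo = Topology(
            bead_role=np.full(n, ROLE_HEAD, np.int8),
            bonds=np.zeros((0, 2), np.int64), bond_r0=[], bond_k=[],
            lipid_id=np.arange(n),
            leaflet_of_lipid=np.r_[np.zeros(per_leaflet, np.int8),
                                   np.ones(per_leaflet, np.int8)],
            director_pairs=np.zeros((0, 2), np.int64), director_lipid=[],
        )
        return frame, topo

    def test_direct_arithmetic(self):
        frame, topo = self._system(120)
        assert area_per_lipid(frame, topo) == pytest.approx(109.8**2 / 120)

    def test_doubling_area_doubles_value(self):
        frame, topo = self._system(10)
        a0 = area_per_lipid(frame, topo)
        frame.box[0] *= 2
        assert area_per_lipid(frame, topo) == pytest.approx(2 * a0)

    def test_one_lipid_per_leaflet(self):
        frame, topo = self._system(1)
        assert area_per_lipid(frame, topo) == pytest.approx(109.8**2)

    def test_sterol_exclusion(self):
        frame, topo = self._system(10, sterols=2)
        assert area_per_lipid(frame, topo, exclude_sterol=True) == \
            pytest.approx(109.8**2 / 8)


class TestPressure:
    def test_ideal_gas_law(self, solvent_frame, free_topology):
        frame, _ = solvent_frame
        topo = free_topology(frame.n_particles)
        ff = ForceField(repulsion=np.zeros((3, 3)))
        p = mean_pressure(frame, topo, ff)
        t_inst = frame.kinetic_temperature()
        expected = internal_pressure_to_gpa(
            frame.n_particles * KB * t_inst / frame.volume)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_static_non_interacting_zero(self, free_topology):
        frame = _bare_frame([[10.0, 10.0, 10.0], [20.0, 20.0, 20.0]])
        ff = ForceField(repulsion=np.zeros((3, 3)))
        assert mean_pressure(frame, free_topology(2), ff) == 0.0

    def test_bond_at_rest_length_adds_nothing(self):
        pos = [[10.0, 10.0, 10.0], [10.0, 10.0, 15.0]]
        frame = _bare_frame(pos, vel=np.array([[0, 0, 1.0], [0, 0, -1.0]]))
        topo = Topology(
            bead_role=np.full(2, ROLE_HEAD, np.int8),
            bonds=np.array([[0, 1]]), bond_r0=[5.0], bond_k=[1000.0],
            lipid_id=np.zeros(2), leaflet_of_lipid=[0, 1],
            director_pairs=np.zeros((0, 2), np.int64), director_lipid=[],
        )
        ff = ForceField(repulsion=np.zeros((3, 3)))
        kin_only = internal_pressure_to_gpa(
            2 * frame.kinetic_energy() / 3 / frame.volume)
        assert mean_pressure(frame, topo, ff) == pytest.approx(kin_only,
                                                               rel=1e-12)

    def test_local_profile_volume_average_is_global(self, small_membrane):
        """Consistency oracle: sum P_bin V_bin / V == global virial P."""
        frame, topo, ff = small_membrane
        prof = local_pressure_profile(frame, topo, ff, 5.0)
        vbin = frame.lateral_area * prof.bin_width
        avg = float(np.sum(prof.pressure * vbin)) / frame.volume
        assert avg == pytest.approx(mean_pressure(frame, topo, ff), rel=1e-6)

    def test_homogeneous_fluid_flat_profile(self, solvent_frame):
        frame, topo = solvent_frame
        from memshock import equilibrate, default_forcefield
        ff = default_forcefield()
        eq, _ = equilibrate(frame, topo, ff, 310.0, 800, seed=8)
        lz = eq.box[2]
        bw = lz / 6
        prof = local_pressure_profile(eq, topo, ff, bw)
        assert prof.pressure.std() < 0.35 * abs(prof.pressure.mean())

    def test_streaming_correction_removes_flow(self, free_topology):
        rng = np.random.default_rng(9)
        pos = np.c_[rng.uniform(0, 50, (400, 2)), rng.uniform(0, 100, 400)]
        vel = np.zeros((400, 3))
        vel[:, 2] = 30.0   # pure bulk flow, no thermal motion
        frame = _bare_frame(pos, vel=vel)
        ff = ForceField(repulsion=np.zeros((3, 3)))
        raw = local_pressure_profile(frame, free_topology(400), ff, 10.0)
        cor = local_pressure_profile(frame, free_topology(400), ff, 10.0,
                                     streaming_corrected=True)
        assert raw.pressure.sum() > 0
        assert np.allclose(cor.pressure, 0.0, atol=1e-12)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        s = MetricSeries(np.arange(10) * 0.1, np.full(10, 3.3), "x")
        out = moving_average(s, 0.25)
        assert np.allclose(out.smoothed, 3.3)

    def test_impulse_spread_conserves_sum(self):
        n = 21
        vals = np.zeros(n)
        vals[10] = 1.0
        s = MetricSeries(np.arange(n) * 0.1, vals, "x")
        out = moving_average(s, 0.5)
        # discrete convolution oracle: away from edges the boxcar is
        # mass-preserving
        assert out.smoothed.sum() == pytest.approx(1.0, rel=1e-9)

    def test_window_equal_to_duration_gives_global_mean(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=9)
        s = MetricSeries(np.arange(9.0), vals, "x")
        out = moving_average(s, 1000.0)
        assert np.allclose(out.smoothed, vals.mean())

    def test_window_below_sampling_rejected(self):
        s = MetricSeries([0.0, 1.0], [1.0, 2.0], "x")
        with pytest.raises(MetricError):
            moving_average(s, 0.5)


class TestShockSpeed:
    def _profiles(self, speed_A_ps, times, z0=20.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        profs = []
        centers = (np.arange(40) + 0.5) * 5.0
        for t in times:
            z = z0 + speed_A_ps * t + noise * 5.0 * rng.standard_normal()
            p = np.exp(-0.5 * ((centers - z) / 6.0) ** 2)
            profs.append(PressureProfile(centers, p, 5.0, t))
        return profs

    def test_constant_speed_track(self):
        profs = self._profiles(30.0, np.arange(6) * 0.2)
        fit = shock_speed(profs)
        assert fit.speed_km_s == pytest.approx(3.0, rel=0.02)
        assert fit.r_squared > 0.99

    def test_static_peak(self):
        profs = self._profiles(0.0, np.arange(5) * 0.2)
        assert abs(shock_speed(profs).speed_A_ps) < 1e-6

    def test_noisy_track_within_five_percent(self):
        profs = self._profiles(30.0, np.arange(20) * 0.2, noise=1.0, seed=5)
        with pytest.warns(UserWarning):
            fit = shock_speed(profs)
        assert fit.speed_A_ps == pytest.approx(30.0, rel=0.05)

    def test_too_few_profiles(self):
        with pytest.raises(MetricError):
            shock_speed(self._profiles(30.0, [0.0, 0.1]))


class TestResponseTime:
    def test_onset_before_drifted_minimum(self):
        t = np.arange(0, 10, 0.1)
        # sharp dip at t=2 on top of a slow downward drift whose global
        # minimum sits at the end of the record
        vals = 1.0 - 0.3 * np.exp(-((t - 2) / 0.3) ** 2) - 0.04 * t
        s = MetricSeries(t, vals, "x")
        rt = response_time(s)
        assert 1.0 < rt < 2.5

    def test_flat_series_returns_duration(self):
        s = MetricSeries(np.arange(5.0), np.ones(5), "x")
        assert response_time(s, window=2.0) == pytest.approx(4.0)
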