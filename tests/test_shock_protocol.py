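"""Shock prescription: nominal pulse relations, slab selection, injection."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memshock import (ShockSpec, added_velocity, nominal_pulse_duration,
                      nominal_peak_pressure, loading_rate, select_slab,
                      apply_shock, zero_net_momentum)
from memshock.shock import ShockDomainError, SlabRangeError, EmptySlabWarning
from memshock.system import ParticleFrame, Topology


def _frame_of_solvent(z_positions, box=(20.0, 20.0, 20.0), mass=72.0):
    n = len(z_positions)
    pos = np.zeros((n, 3))
    pos[:, 2] = z_positions
    return ParticleFrame(pos, np.zeros((n, 3)), np.full(n, mass),
                         np.array(["W"] * n), np.arange(n), np.array(box)), \
        Topology(np.zeros(n, np.int8), np.zeros((0, 2), np.int64), [], [],
                 np.full(n, -1), [0, 1], np.zeros((0, 2), np.int64), [])


class TestNominalRelations:
    # dv_z = I/(rho L_w): direct-arithmetic oracle values
    @pytest.mark.parametrize("impulse,rho,lw,expected", [
        (1e-3, 1000.0, 5e-10, 2000.0),
        (1e-2, 1000.0, 3e-9, 1e-2 / (1000.0 * 3e-9)),  # 3333.33 m/s
    ])
    def test_added_velocity(self, impulse, rho, lw, expected):
        assert added_velocity(impulse, rho, lw) == pytest.approx(expected,
                                                                 rel=1e-12)

    def test_added_velocity_vanishes_with_impulse(self):
        assert added_velocity(1e-30, 1000.0, 5e-10) == pytest.approx(0.0,
                                                                     abs=1e-15)

    @pytest.mark.parametrize("lw_A,dv,expected_ps", [
        (5.0, 2000.0, 0.25),
        (30.0, 1000.0 / 3.0, 9.0),
        (5.0, 20000.0, 0.025),
    ])
    def test_pulse_duration(self, lw_A, dv, expected_ps):
        tp = nominal_pulse_duration(lw_A * 1e-10, dv)
        assert tp / 1e-12 == pytest.approx(expected_ps, rel=1e-9)

    @pytest.mark.parametrize("rho,dv,expected_GPa", [
        (1000.0, 2000.0, 4.0),
        (1000.0, 20000.0, 400.0),
    ])
    def test_peak_pressure(self, rho, dv, expected_GPa):
        assert nominal_peak_pressure(rho, dv) * 1e-9 == pytest.approx(
            expected_GPa, rel=1e-12)

    def test_peak_pressure_zero_velocity(self):
        assert nominal_peak_pressure(1000.0, 0.0) == 0.0

    @pytest.mark.parametrize("tp_ps,expected_per_ps", [
        (0.25, 4.0), (1.0, 1.0), (0.9, 1.0 / 0.9),
    ])
    def test_loading_rate(self, tp_ps, expected_per_ps):
        assert loading_rate(tp_ps * 1e-12) * 1e-12 == pytest.approx(
            expected_per_ps, rel=1e-12)

    @pytest.mark.parametrize("func,args", [
        (added_velocity, (0.0, 1000.0, 5e-10)),
        (added_velocity, (1e-3, -1.0, 5e-10)),
        (nominal_pulse_duration, (5e-10, 0.0)),
        (nominal_peak_pressure, (-1.0, 10.0)),
        (loading_rate, (0.0,)),
    ])
    def test_domain_errors(self, func, args):
        with pytest.raises(ShockDomainError):
            func(*args)


class TestShockSpec:
    @given(impulse=st.floats(1e-5, 1.0), lw_A=st.floats(0.5, 100.0),
           rho=st.floats(500.0, 2000.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_pulse_identities(self, impulse, lw_A, rho):
        """t_p * P_n == I and gamma * t_p == 1 for every constructible spec."""
        spec = ShockSpec(impulse=impulse, slab_thickness=lw_A * 1e-10,
                         water_density=rho)
        assert spec.pulse_duration * spec.peak_pressure == pytest.approx(
            spec.impulse, rel=1e-12)
        assert spec.loading_rate * spec.pulse_duration == pytest.approx(
            1.0, rel=1e-15)
        assert spec.added_velocity == pytest.approx(
            spec.impulse / (rho * spec.slab_thickness), rel=1e-12)

    def test_doubling_slab_halves_velocity(self):
        a = ShockSpec.from_angstrom(1.0, 10.0)
        b = ShockSpec.from_angstrom(1.0, 20.0)
        assert b.added_velocity == pytest.approx(a.added_velocity / 2)
        assert b.pulse_duration == pytest.approx(4 * a.pulse_duration)
        assert b.peak_pressure == pytest.approx(a.peak_pressure / 4)

    def test_config_round_trip(self):
        spec = ShockSpec.from_angstrom(10.0, 15.0, gap_A=7.5)
        blk = spec.to_config()
        assert blk["impulse_mPa_s"] == pytest.approx(10.0)
        back = ShockSpec.from_config(blk)
        for attr in ("impulse", "slab_thickness", "gap", "water_density"):
            assert getattr(back, attr) == pytest.approx(getattr(spec, attr),
                                                        rel=1e-12)
        # derived block is consistent with the relations
        d = blk["derived"]
        # GPa * ps = 1e-3 Pa s
        assert d["pulse_duration_ps"] * d["peak_pressure_GPa"] * 1e-3 \
            == pytest.approx(spec.impulse, rel=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ShockDomainError):
            ShockSpec(impulse=-1e-3, slab_thickness=5e-10)
        with pytest.raises(ShockDomainError):
            ShockSpec(impulse=1e-3, slab_thickness=5e-10, gap=-1e-10)


class TestSelectSlab:
    def test_whole_molecule_membership(self):
        # brute-force membership oracle: molecules at z = 1, 6, 11
        frame, topo = _frame_of_solvent([1.0, 6.0, 11.0])
        ids = select_slab(frame, topo, 0.0, 10.0)
        assert sorted(ids.tolist()) == [0, 1]

    def test_total_inclusion_and_empty_interval(self):
        frame, topo = _frame_of_solvent([2.0, 5.0, 18.0])
        assert sorted(select_slab(frame, topo, 0.0, 20.0).tolist()) == [0, 1, 2]
        with pytest.warns(EmptySlabWarning):
            ids = select_slab(frame, topo, 5.0, 0.0)
        assert len(ids) == 0

    def test_half_open_interval_partitions(self):
        frame, topo = _frame_of_solvent([5.0, 10.0, 15.0])
        low = select_slab(frame, topo, 0.0, 10.0)
        high = select_slab(frame, topo, 10.0, 10.0)
        both = sorted(np.concatenate([low, high]).tolist())
        assert both == [0, 1, 2]  # no double counting at the boundary

    def test_non_solvent_never_selected(self):
        frame, topo = _frame_of_solvent([5.0, 6.0, 7.0])
        topo.bead_role[1] = 2  # make a tail bead
        ids = select_slab(frame, topo, 0.0, 20.0)
        assert 1 not in ids

    def test_out_of_box_slab(self):
        frame, topo = _frame_of_solvent([5.0])
        with pytest.raises(SlabRangeError):
            select_slab(frame, topo, 15.0, 10.0)


class TestApplyShock:
    def test_momentum_bookkeeping(self):
        # brute-force sum oracle: N equal masses -> dp_z = N m dv_z
        rng = np.random.default_rng(0)
        frame, topo = _frame_of_solvent(rng.uniform(0, 20, 100))
        frame.velocities = rng.normal(0, 2, (100, 3))
        spec = ShockSpec.from_angstrom(1.0, 30.0)
        ids = np.arange(100)
        p0 = frame.momentum()
        out = apply_shock(frame, spec, ids)
        p1 = out.momentum()
        dv = spec.added_velocity_A_ps
        expected = np.sum(frame.masses * dv)
        assert p1[2] - p0[2] == pytest.approx(expected, rel=1e-13)
        # x-, y-momentum conserved exactly; positions bit-identical
        assert p1[0] == p0[0] and p1[1] == p0[1]
        assert np.array_equal(out.positions, frame.positions)
        # untouched particles: none here, so check via partial slab
        out2 = apply_shock(frame, spec, np.array([3]))
        mask = np.ones(100, bool)
        mask[3] = False
        assert np.array_equal(out2.velocities[mask], frame.velocities[mask])

    def test_empty_slab_rejected(self):
        frame, _ = _frame_of_solvent([5.0])
        spec = ShockSpec.from_angstrom(1.0, 5.0)
        with pytest.raises(ShockDomainError):
            apply_shock(frame, spec, np.array([], dtype=np.int64))

    def test_zero_net_momentum(self):
        rng = np.random.default_rng(1)
        frame, _ = _frame_of_solvent(rng.uniform(0, 20, 50))
        frame.velocities = rng.normal(1.0, 2.0, (50, 3))
        out = zero_net_momentum(frame)
        assert np.allclose(out.momentum(), 0.0, atol=1e-9)
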