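"""Force laws: worked examples, momentum sums, finite-difference oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melanosim.forces import (
    confinement_force,
    filament_energy,
    filament_internal_forces,
    link_force,
    motor_force,
    pair_repulsion,
)
from melanosim.state import CellSpace, FilamentState, MotorState


def straight_filament(nv=5, s0=0.5, host=-1, anchor=None):
    x = np.zeros((nv, 2))
    x[:, 0] = s0 * np.arange(nv)
    rest = np.full(nv - 1, s0)
    return FilamentState(id=0, vertices=x, rest_lengths=rest,
                         length=s0 * (nv - 1), host=host,
                         anchor_offset=anchor)


class TestPairRepulsion:
    def test_overlap_magnitude_hand_example(self):
        # Disks of radius 0.25 at distance 0.3: overlap 0.2, k=30 -> 6 pN
        fA, fB = pair_repulsion([0.0, 0.0], [0.3, 0.0], 0.25, 0.25, 30.0)
        assert fA == pytest.approx([-6.0, 0.0])
        assert fB == pytest.approx([6.0, 0.0])

    def test_zero_beyond_contact(self):
        fA, fB = pair_repulsion([0.0, 0.0], [0.6, 0.0], 0.25, 0.25, 30.0)
        assert np.all(fA == 0.0) and np.all(fB == 0.0)

    def test_equal_and_opposite_random_geometry(self, rng):
        for _ in range(20):
            pa, pb = rng.normal(size=2), rng.normal(size=2)
            fA, fB = pair_repulsion(pa, pb, 0.4, 0.7, 30.0)
            assert fA + fB == pytest.approx([0.0, 0.0], abs=0.0)

    def test_coincident_centres_fall_back_to_x(self):
        fA, _ = pair_repulsion([1.0, 1.0], [1.0, 1.0], 0.25, 0.25, 30.0)
        assert fA[1] == 0.0 and fA[0] == pytest.approx(15.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pair_repulsion([np.nan, 0], [0, 0], 0.25, 0.25, 30.0)
        with pytest.raises(ValueError):
            pair_repulsion([0, 0], [1, 0], -0.25, 0.25, 30.0)


class TestConfinement:
    CELL = CellSpace(R=10.0, k_wall=30.0)

    def test_zero_inside(self):
        assert confinement_force([5.0, 0.0], 0.25, self.CELL) == (
            pytest.approx([0.0, 0.0])
        )

    def test_penetration_hand_example(self):
        # |pos| + a = 10.05 -> excess 0.05, F = 30*0.05 = 1.5 pN inward
        f = confinement_force([9.8, 0.0], 0.25, self.CELL)
        assert f == pytest.approx([-1.5, 0.0])

    def test_radial_direction(self, rng):
        pos = 9.9 * np.array([np.cos(1.1), np.sin(1.1)])
        f = confinement_force(pos, 0.25, self.CELL)
        # anti-parallel to the position vector
        assert f[0] * pos[1] - f[1] * pos[0] == pytest.approx(0.0, abs=1e-12)
        assert np.dot(f, pos) < 0


class TestFilamentInternal:
    S0, KAPPA, KSEG = 0.5, 0.042, 30.0

    def test_straight_at_rest_is_force_free(self):
        f = filament_internal_forces(straight_filament(), self.S0,
                                     self.KAPPA, self.KSEG)
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-12)

    def test_stretched_two_vertex_hand_example(self):
        # One segment of rest 0.5 stretched to 0.6: |F| = 30*0.1 = 3 pN
        fil = FilamentState(id=0, vertices=np.array([[0.0, 0.0], [0.6, 0.0]]),
                            rest_lengths=np.array([0.5]), length=0.5)
        f = filament_internal_forces(fil, self.S0, 0.0, self.KSEG)
        assert f[0] == pytest.approx([3.0, 0.0])
        assert f[1] == pytest.approx([-3.0, 0.0])

    def test_total_force_and_torque_vanish(self, rng):
        """Internal forces can impart no net force or torque."""
        for _ in range(10):
            nv = 6
            x = np.cumsum(rng.normal(0.5, 0.2, size=(nv, 2)), axis=0)
            fil = FilamentState(id=0, vertices=x,
                                rest_lengths=np.full(nv - 1, self.S0),
                                length=self.S0 * (nv - 1))
            f = filament_internal_forces(fil, self.S0, self.KAPPA, self.KSEG)
            assert f.sum(axis=0) == pytest.approx([0.0, 0.0], abs=1e-10)
            torque = np.sum(x[:, 0] * f[:, 1] - x[:, 1] * f[:, 0])
            assert torque == pytest.approx(0.0, abs=1e-10)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_finite_difference_oracle(self, seed):
        """Analytic forces match -dE/dx of the independent energy to
        first order, for arbitrary bent and stretched shapes."""
        local = np.random.Generator(np.random.PCG64(seed))
        nv = int(local.integers(3, 7))
        x = np.cumsum(local.normal(0.4, 0.15, size=(nv, 2)), axis=0)
        rest = np.full(nv - 1, self.S0)
        fil = FilamentState(id=0, vertices=x, rest_lengths=rest,
                            length=rest.sum())
        f = filament_internal_forces(fil, self.S0, self.KAPPA, self.KSEG)
        h = 1e-6
        for i in range(nv):
            for k in range(2):
                xp, xm = x.copy(), x.copy()
                xp[i, k] += h
                xm[i, k] -= h
                num = -(filament_energy(xp, rest, self.S0, self.KAPPA,
                                        self.KSEG)
                        - filament_energy(xm, rest, self.S0, self.KAPPA,
                                          self.KSEG)) / (2 * h)
                assert f[i, k] == pytest.approx(num, abs=2e-4)

    def test_degenerate_segment_rejected(self):
        fil = FilamentState(id=0,
                            vertices=np.array([[0.0, 0.0], [0.0, 0.0]]),
                            rest_lengths=np.array([0.5]), length=0.5)
        with pytest.raises(ValueError):
            filament_internal_forces(fil, self.S0, self.KAPPA, self.KSEG)


class TestLinkForce:
    def test_hand_example_and_reaction(self):
        anchor = np.array([0.25, 0.0])
        fil = straight_filament(host=3, anchor=anchor)
        # organelle at (-0.35, 0): anchor point (-0.1, 0), vertex0 (0,0)
        f0, f_org = link_force(fil, [-0.35, 0.0], 30.0)
        assert f0 == pytest.approx([-3.0, 0.0])
        assert f_org == pytest.approx([3.0, 0.0])

    def test_unattached_rejected(self):
        with pytest.raises(ValueError):
            link_force(straight_filament(), [0.0, 0.0], 30.0)


class TestMotorForce:
    def test_midsegment_split_and_reaction(self):
        fil = straight_filament(nv=3, s0=0.5)
        motor = MotorState(id=0, host=0,
                           anchor_offset=np.array([0.0, 0.25]),
                           bound_filament=0, arc_s=0.25)
        # organelle at (0.25, 0.15): anchor (0.25, 0.40), track (0.25, 0)
        f_org, per_vertex = motor_force(motor, fil, [0.25, 0.15], 30.0)
        f_point = 30.0 * np.array([0.0, 0.40])
        assert f_org == pytest.approx(-f_point)
        assert per_vertex.sum(axis=0) == pytest.approx(f_point)
        # arc 0.25 sits halfway along segment 0: equal split, none on v2
        assert per_vertex[0] == pytest.approx(f_point / 2)
        assert per_vertex[1] == pytest.approx(f_point / 2)
        assert per_vertex[2] == pytest.approx([0.0, 0.0])

    def test_vertex_coincident_arc(self):
        fil = straight_filament(nv=3, s0=0.5)
        motor = MotorState(id=0, host=0,
                           anchor_offset=np.zeros(2),
                           bound_filament=0, arc_s=0.5)
        f_org, per_vertex = motor_force(motor, fil, [0.5, 0.3], 30.0)
        assert per_vertex[1] == pytest.approx([0.0, 9.0])
        assert f_org == pytest.approx([0.0, -9.0])

    def test_unbound_and_out_of_range_rejected(self):
        fil = straight_filament(nv=3, s0=0.5)
        free = MotorState(id=0, host=0, anchor_offset=np.zeros(2))
        with pytest.raises(ValueError):
            motor_force(free, fil, [0.0, 0.0], 30.0)
        bad = MotorState(id=0, host=0, anchor_offset=np.zeros(2),
                         bound_filament=0, arc_s=5.0)
        with pytest.raises(ValueError):
            motor_force(bad, fil, [0.0, 0.0], 30.0)
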