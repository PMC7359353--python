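"""Kinetic phases: nucleation, growth, turnover, motor cycling."""

import math

import numpy as np
import pytest

from melanosim import SimConfig, run_simulation
from melanosim.kinetics import (
    grow_filaments,
    motor_bind,
    motor_unbind,
    motor_walk,
    nucleate_filaments,
    turnover_filaments,
)
from melanosim.state import FREE, CellSpace, SystemState


def cfg_with(**over):
    base = {"n_organelles": 1, "motors_per_organelle": 1, "seed": 0}
    base.update(over)
    return SimConfig(**base).validate()


def bare_state(cfg, org_pos, motor_offsets=None):
    """State with explicit organelle positions and motor anchor offsets
    (one motor per (host, offset) pair)."""
    org_pos = np.atleast_2d(np.asarray(org_pos, dtype=float))
    n = len(org_pos)
    if motor_offsets is None:
        motor_offsets = []
    hosts = np.array([h for h, _ in motor_offsets], dtype=np.int64)
    offs = np.array([o for _, o in motor_offsets], dtype=float).reshape(-1, 2)
    gamma = np.full(n, 6 * np.pi * 0.3 * cfg.organelle_radius)
    return SystemState(
        CellSpace(cfg.R, cfg.k_wall), org_pos,
        np.full(n, cfg.organelle_radius), gamma, hosts, offs,
        max_vertices=cfg.max_vertices,
    )


def add_filament(state, vertices, host=FREE, origin=0, anchor=(0.0, 0.0)):
    f = state.n_fil
    state.ensure_filament_capacity(f + 1)
    vertices = np.asarray(vertices, dtype=float)
    nv = len(vertices)
    rest = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    state.fil_active[f] = 1
    state.fil_nv[f] = nv
    state.fil_x[f, :nv] = vertices
    state.fil_rest[f, : nv - 1] = rest
    state.fil_length[f] = rest.sum()
    state.fil_host[f] = host
    state.fil_origin[f] = origin
    state.fil_anchor[f] = anchor
    state.n_fil += 1
    return f


class TestNucleation:
    def test_zero_rate_never_nucleates(self, rng):
        cfg = cfg_with(nucleation_rate=0.0)
        state = bare_state(cfg, [[0.0, 0.0]])
        for _ in range(200):
            assert nucleate_filaments(state, cfg, rng) == 0
        assert state.n_fil == 0

    def test_poisson_count_oracle(self, rng):
        """60 organelles, 1e4 steps at r_nuc=0.05/s, dt=1e-3: total count
        is Binomial(6e5, 1-exp(-5e-5)), mean 30 — check within 3 sigma."""
        cfg = cfg_with(n_organelles=60, nucleation_rate=0.05,
                       filament_lifetime=float("inf"))
        state = bare_state(cfg, np.zeros((60, 2)))
        state.org_pos[:, 0] = np.linspace(-8, 8, 60)
        state.ensure_filament_capacity(256)
        total = sum(nucleate_filaments(state, cfg, rng)
                    for _ in range(10_000))
        n_trials = 60 * 10_000
        p = 1.0 - math.exp(-cfg.nucleation_rate * cfg.dt)
        mean, sigma = n_trials * p, math.sqrt(n_trials * p * (1 - p))
        assert abs(total - mean) <= 3 * sigma
        assert state.n_fil == total

    def test_attached_geometry_at_creation(self, rng):
        """Pointed end on the host surface at the anchor point, directed
        along the outward normal, length ell0."""
        cfg = cfg_with(nucleation_rate=1e6, mode="attached")
        state = bare_state(cfg, [[2.0, -1.0]])
        assert nucleate_filaments(state, cfg, rng) == 1
        fil = state.filament(0)
        anchor_world = state.org_pos[0] + fil.anchor_offset
        assert fil.vertices[0] == pytest.approx(anchor_world)
        assert np.linalg.norm(fil.anchor_offset) == pytest.approx(
            cfg.organelle_radius
        )
        seg = fil.vertices[1] - fil.vertices[0]
        assert np.linalg.norm(seg) == pytest.approx(cfg.initial_length)
        # outward normal: segment parallel to the anchor offset
        cross = seg[0] * fil.anchor_offset[1] - seg[1] * fil.anchor_offset[0]
        assert cross == pytest.approx(0.0, abs=1e-12)
        assert np.dot(seg, fil.anchor_offset) > 0

    def test_detached_mode_never_links(self, rng):
        cfg = cfg_with(nucleation_rate=1e6, mode="detached")
        state = bare_state(cfg, [[0.0, 0.0]])
        nucleate_filaments(state, cfg, rng)
        assert state.fil_host[0] == FREE
        assert state.fil_origin[0] == 0  # provenance still recorded


class TestGrowth:
    def test_exact_elongation_law(self, rng):
        cfg = cfg_with(nucleation_rate=1e6, growth_speed=0.1)
        state = bare_state(cfg, [[0.0, 0.0]])
        nucleate_filaments(state, cfg, rng)
        for k in range(1, 501):
            grow_filaments(state, cfg)
            expected = min(cfg.initial_length + k * 0.1 * cfg.dt,
                           cfg.max_length)
            assert state.fil_length[0] == pytest.approx(expected, rel=1e-9)

    def test_caps_at_max_length(self, rng):
        cfg = cfg_with(nucleation_rate=1e6, growth_speed=0.3)
        state = bare_state(cfg, [[0.0, 0.0]])
        nucleate_filaments(state, cfg, rng)
        for _ in range(20_000):
            grow_filaments(state, cfg)
        assert state.fil_length[0] == pytest.approx(cfg.max_length)

    def test_vertex_bookkeeping(self, rng):
        """Rest lengths stay in (0, 1.5*s0], sum to the contour length,
        and the vertex count tracks 1 + L/s0."""
        cfg = cfg_with(nucleation_rate=1e6, growth_speed=0.3)
        state = bare_state(cfg, [[0.0, 0.0]])
        nucleate_filaments(state, cfg, rng)
        s0 = cfg.segment_length
        for _ in range(10_000):
            grow_filaments(state, cfg)
            nv = int(state.fil_nv[0])
            rest = state.fil_rest[0, : nv - 1]
            L = state.fil_length[0]
            assert np.all(rest > 0)
            assert np.all(rest <= 1.5 * s0 + 1e-9)
            assert rest.sum() == pytest.approx(L, rel=1e-9)
            assert nv <= 2 + math.ceil(L / s0)

    def test_zero_growth_speed(self, rng):
        cfg = cfg_with(nucleation_rate=1e6, growth_speed=0.0)
        state = bare_state(cfg, [[0.0, 0.0]])
        nucleate_filaments(state, cfg, rng)
        for _ in range(100):
            grow_filaments(state, cfg)
        assert state.fil_length[0] == pytest.approx(cfg.initial_length)


class TestTurnover:
    def test_infinite_lifetime_is_inert(self, rng):
        cfg = cfg_with(filament_lifetime=float("inf"))
        state = bare_state(cfg, [[0.0, 0.0]])
        add_filament(state, [[1.0, 0.0], [1.5, 0.0]])
        for _ in range(100):
            assert turnover_filaments(state, cfg, rng) == 0

    def test_deletion_count_binomial_oracle(self, rng):
        """Per-step deletion probability 1-exp(-dt/tau); realized count
        over accumulated exposures is Binomial — check within 3 sigma."""
        cfg = cfg_with(filament_lifetime=2.0)
        state = bare_state(cfg, [[0.0, 0.0]])
        for i in range(400):
            add_filament(state, [[1.0 + 0.01 * i, 0.0],
                                 [1.5 + 0.01 * i, 0.0]])
        p = 1.0 - math.exp(-cfg.dt / 2.0)
        exposures = deleted = 0
        for _ in range(4000):
            exposures += len(state.active_filaments)
            deleted += turnover_filaments(state, cfg, rng)
        mean = exposures * p
        sigma = math.sqrt(exposures * p * (1 - p))
        assert abs(deleted - mean) <= 3 * sigma

    def test_bound_motors_released_on_deletion(self, rng):
        cfg = cfg_with(filament_lifetime=1e-9)  # p ~ 1
        state = bare_state(cfg, [[0.0, 0.0]], [(0, (0.0, 0.25))])
        f = add_filament(state, [[1.0, 0.0], [2.0, 0.0]])
        state.motor_fil[0] = f
        state.motor_s[0] = 0.5
        assert turnover_filaments(state, cfg, rng) == 1
        assert state.motor_fil[0] == FREE
        assert state.motor_s[0] == 0.0
        state.check_integrity()


class TestMotorBind:
    def test_no_filament_in_range_stays_free(self, rng):
        cfg = cfg_with(k_on=1e6)
        state = bare_state(cfg, [[0.0, 0.0]], [(0, (0.0, 0.25))])
        add_filament(state, [[5.0, 5.0], [6.0, 5.0]])
        assert motor_bind(state, cfg, rng) == 0
        assert state.motor_fil[0] == FREE

    def test_binds_at_perpendicular_foot(self, rng):
        """Anchor 0.05 um above a straight track: binds at the foot
        point, arc coordinate = distance from the pointed end."""
        cfg = cfg_with(k_on=1e6)
        state = bare_state(cfg, [[2.0, 0.0]],
                           [(0, (0.0, 0.05))])  # anchor (2.0, 0.05)
        f = add_filament(state, [[1.0, 0.0], [2.5, 0.0], [4.0, 0.0]],
                        origin=99)
        assert motor_bind(state, cfg, rng) == 1
        assert state.motor_fil[0] == f
        assert state.motor_s[0] == pytest.approx(1.0)

    def test_closest_filament_wins(self, rng):
        cfg = cfg_with(k_on=1e6)
        state = bare_state(cfg, [[2.0, 0.0]], [(0, (0.0, 0.02))])
        add_filament(state, [[1.0, 0.09], [3.0, 0.09]], origin=99)
        near = add_filament(state, [[1.0, 0.05], [3.0, 0.05]], origin=99)
        motor_bind(state, cfg, rng)
        assert state.motor_fil[0] == near

    def test_self_binding_flag(self, rng):
        cfg = cfg_with(k_on=1e6, allow_self_binding=False)
        state = bare_state(cfg, [[2.0, 0.0]], [(0, (0.0, 0.05))])
        add_filament(state, [[1.0, 0.0], [3.0, 0.0]], origin=0)  # own
        assert motor_bind(state, cfg, rng) == 0
        other = add_filament(state, [[1.0, 0.0], [3.0, 0.0]], origin=7)
        assert motor_bind(state, cfg, rng) == 1
        assert state.motor_fil[0] == other

    def test_binding_frequency_bernoulli_oracle(self, rng):
        """With a permanently in-range track, binds per step over 1e4
        trials realize Binomial(1e4, 1-exp(-k_on*dt)) within 3 sigma."""
        cfg = cfg_with(k_on=5.0)
        state = bare_state(cfg, [[2.0, 0.0]], [(0, (0.0, 0.05))])
        add_filament(state, [[1.0, 0.0], [3.0, 0.0]], origin=99)
        n, binds = 10_000, 0
        for _ in range(n):
            binds += motor_bind(state, cfg, rng)
            state.motor_fil[0] = FREE   # re-arm
            state.motor_s[0] = 0.0
        p = 1.0 - math.exp(-5.0 * cfg.dt)
        assert abs(binds - n * p) <= 3 * math.sqrt(n * p * (1 - p))


class TestMotorWalk:
    def bound_setup(self, anchor_dx, k_motor=30.0, s=1.0):
        """Motor bound at arc s on a straight +x track; the anchor sits
        anchor_dx along x from the track point (negative = behind)."""
        cfg = cfg_with(k_motor=k_motor)
        track_x = 1.0 + s
        state = bare_state(
            cfg, [[track_x + anchor_dx, 0.0]], [(0, (0.0, 0.0))]
        )
        f = add_filament(state, [[1.0, 0.0], [2.5, 0.0], [4.0, 0.0]])
        state.motor_fil[0] = f
        state.motor_s[0] = s
        return cfg, state

    def test_unloaded_speed(self):
        cfg, state = self.bound_setup(anchor_dx=0.0)
        motor_walk(state, cfg)
        assert state.motor_s[0] == pytest.approx(1.0 + cfg.v_motor * cfg.dt)

    def test_stall(self):
        # resisting load k*dx = 30*0.1 = 3 pN = F_stall -> no motion
        cfg, state = self.bound_setup(anchor_dx=-0.1)
        motor_walk(state, cfg)
        assert state.motor_s[0] == pytest.approx(1.0)

    def test_half_load_half_speed(self):
        cfg, state = self.bound_setup(anchor_dx=-0.05)
        motor_walk(state, cfg)
        assert state.motor_s[0] == pytest.approx(
            1.0 + 0.5 * cfg.v_motor * cfg.dt
        )

    def test_assisting_load_capped_at_unloaded_speed(self):
        cfg, state = self.bound_setup(anchor_dx=+0.2)
        motor_walk(state, cfg)
        assert state.motor_s[0] == pytest.approx(1.0 + cfg.v_motor * cfg.dt)

    def test_super_stall_load_clamps_at_zero(self):
        cfg, state = self.bound_setup(anchor_dx=-0.5)  # 15 pN >> stall
        motor_walk(state, cfg)
        assert state.motor_s[0] == pytest.approx(1.0)

    def test_end_detachment(self):
        cfg, state = self.bound_setup(anchor_dx=0.0, s=2.9999)
        detached = motor_walk(state, cfg)
        assert detached == 1
        assert state.motor_fil[0] == FREE


class TestMotorUnbind:
    def make_bound(self, cfg, n_motors):
        offsets = [(0, (0.0, 0.0))] * n_motors
        state = bare_state(cfg, [[2.0, 0.0]], offsets)
        f = add_filament(state, [[1.0, 0.0], [3.0, 0.0]])
        state.motor_fil[:] = f
        state.motor_s[:] = 1.0
        return state

    def test_zero_rate_never_releases(self, rng):
        cfg = cfg_with(k_off=0.0)
        state = self.make_bound(cfg, 10)
        for _ in range(100):
            assert motor_unbind(state, cfg, rng) == 0

    def test_release_count_binomial_oracle(self, rng):
        """One sweep over 2000 bound motors with per-step release
        probability 0.3 realizes Binomial(2000, 0.3) within 3 sigma."""
        p = 0.3
        cfg = cfg_with(k_off=-math.log(1 - p) / 1e-3)
        state = self.make_bound(cfg, 2000)
        released = motor_unbind(state, cfg, rng)
        assert abs(released - 2000 * p) <= 3 * math.sqrt(2000 * p * (1 - p))
        freed = state.motor_fil == FREE
        assert freed.sum() == released
        assert np.all(state.motor_s[freed] == 0.0)

    def test_bell_law_increases_release_under_load(self, rng):
        """With the optional Bell law on, a stretched motor releases
        faster than a relaxed one (same base k_off)."""
        n = 2000
        counts = {}
        for dx in (0.0, -0.3):
            cfg = cfg_with(k_off=30.0, bell_unbinding=True,
                           bell_force_scale=2.0)
            offsets = [(0, (0.0, 0.0))] * n
            state = bare_state(cfg, [[2.0 + dx, 0.0]], offsets)
            f = add_filament(state, [[1.0, 0.0], [3.0, 0.0]])
            state.motor_fil[:] = f
            state.motor_s[:] = 1.0
            counts[dx] = motor_unbind(state, cfg, rng)
        assert counts[-0.3] > counts[0.0]


class TestFullRunContracts:
    def test_detached_mode_contract(self):
        cfg = SimConfig(mode="detached", n_organelles=15, duration=5.0,
                        seed=2).validate()
        traj = run_simulation(cfg)
        st = traj.final_state
        assert np.all(st.fil_host[st.active_filaments] == FREE)

    def test_polarity_and_integrity_short_attached_run(self):
        cfg = SimConfig(n_organelles=15, duration=5.0, seed=3).validate()
        traj = run_simulation(cfg, log_events=True)
        assert traj.events.polarity_violations == 0
        traj.final_state.check_integrity()

    def test_event_counts_match_log(self):
        cfg = SimConfig(n_organelles=15, duration=5.0, seed=4).validate()
        traj = run_simulation(cfg, log_events=True)
        log = traj.events
        df = log.to_frame()
        for name, count in log.counts.items():
            assert (df["event"] == name).sum() == count
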