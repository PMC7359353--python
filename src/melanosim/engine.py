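"""Time stepping: the overdamped integrator and the top-level run loop.

Dynamics are first-order (inertia-free): every mobile point moves by

    dx = (F / gamma) * dt + sqrt(2 * (kT / gamma) * dt) * xi,

with ``xi`` i.i.d. standard normal per coordinate (Euler-Maruyama).
Organelles translate as rigid disks without rotation; after each step
they are radially projected back to |x| <= R - a, so the confining wall
is both a soft spring during the step and a hard constraint after it.

A run is bit-reproducible: identical (config, seed) gives identical
trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .config import SimConfig
from .kinetics import EventLog, _Buffers
from .state import SystemState

__all__ = ["Trajectory", "integrate_step", "run_simulation"]


@dataclass
class Trajectory:
    """Time series of a run: organelle positions per frame plus extras."""

    config: SimConfig
    times: np.ndarray                     # (F,)
    org_xy: np.ndarray                    # (F, N, 2)
    events: Optional[EventLog] = None
    final_state: Optional[SystemState] = None
    fil_frames: Optional[list] = None     # per frame: (fil_id, sub, x, y)
    motor_frames: Optional[list] = None   # per frame: (id, fil, s)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_organelles(self) -> int:
        return self.org_xy.shape[1]

    def radial_index(self) -> np.ndarray:
        """Mean organelle radius / R, per frame."""
        r = np.linalg.norm(self.org_xy, axis=2)
        return r.mean(axis=1) / self.config.R

    def msd(self) -> np.ndarray:
        """Ensemble mean squared displacement from the first frame."""
        d = self.org_xy - self.org_xy[0]
        return np.mean(np.sum(d * d, axis=2), axis=1)


def integrate_step(
    state: SystemState, config: SimConfig, rng: np.random.Generator
) -> SystemState:
    """One mechanics step (forces + Euler-Maruyama + wall projection).

    Kinetic events are *not* executed here; ``run_simulation`` interleaves
    them.  Mutates and returns ``state``.
    """
    if config.dt > config.stability_bound * (1 + 1e-12):
        raise ValueError(
            f"dt={config.dt:g} above stability bound "
            f"{config.stability_bound:g}"
        )
    buf = _Buffers(state)
    err = _kernel.compute_forces(
        state.org_pos, state.org_rad,
        state.motor_host, state.motor_offset, state.motor_fil, state.motor_s,
        state.fil_active, state.fil_nv, state.fil_x, state.fil_rest,
        state.fil_host, state.fil_anchor, state.n_fil,
        config.R, config.k_wall, config.k_rep, config.k_seg,
        config.k_link, config.k_motor, config.kappa, config.segment_length,
        buf.f_org, buf.f_fil,
    )
    if err:
        raise RuntimeError(f"corrupted filament state (filament {err - 1})")
    err = _kernel.mechanics_phase(
        config.dt, config.kT, config.R, config.k_wall,
        state.org_pos, state.org_rad, state.org_gamma, config.gamma_fil,
        state.fil_active, state.fil_nv, state.fil_x, state.n_fil,
        buf.f_org, buf.f_fil, rng,
    )
    if err:
        _raise_nonfinite(state, err)
    state.time += config.dt
    return state


def _raise_nonfinite(state: SystemState, err: int) -> None:
    n = state.n_organelles
    if err - 1 < n:
        i = err - 1
        raise RuntimeError(
            f"non-finite position for organelle {i}: {state.org_pos[i]}"
        )
    f = err - 1 - n
    raise RuntimeError(
        f"non-finite position on filament {f}: "
        f"{state.fil_x[f, : state.fil_nv[f]]}"
    )


def run_simulation(
    config: SimConfig,
    state: Optional[SystemState] = None,
    *,
    log_events: bool = False,
    record_filaments: bool = False,
    record_motors: bool = False,
) -> Trajectory:
    """Run the full kinetics + mechanics loop and record frames.

    Parameters
    ----------
    config
        Validated simulation parameters (seed included).
    state
        Starting state; by default a perinuclear-clustered population
        from :func:`melanosim.scenarios.make_clustered_start`.
    log_events
        Keep the full kinetic event log (time, kind, ids) instead of
        aggregate counters only.
    record_filaments, record_motors
        Also snapshot filament vertices / motor attachment state per
        frame (organelle positions are always recorded).
    """
    config.validate()
    if state is None:
        from .scenarios import make_clustered_start

        state = make_clustered_start(config)
    rng = np.random.Generator(np.random.PCG64(config.seed))

    dt = config.dt
    total_steps = int(round(config.duration / dt))
    steps_per_frame = max(1, int(round(1.0 / (config.frame_rate * dt))))

    p_nuc = 1.0 - math.exp(-config.nucleation_rate * dt)
    p_del = (
        1.0 - math.exp(-dt / config.filament_lifetime)
        if math.isfinite(config.filament_lifetime)
        else 0.0
    )

    n_events_guess = 0
    if log_events:
        # nucleation + turnover + generous motor-cycling allowance
        n_events_guess = int(
            4 * config.n_organelles * config.nucleation_rate
            * max(config.duration, 1.0)
            + 4 * config.n_organelles * config.motors_per_organelle
            * max(config.k_on, config.k_off) * max(config.duration, 1.0)
            + 1024
        )
    buf = _Buffers(state, capacity=n_events_guess)

    times = [state.time]
    frames = [state.org_pos.copy()]
    fil_frames = [_snapshot_filaments(state)] if record_filaments else None
    motor_frames = [_snapshot_motors(state)] if record_motors else None

    done = 0
    while done < total_steps:
        chunk = min(steps_per_frame, total_steps - done)
        if total_steps - done - chunk < steps_per_frame:
            chunk = total_steps - done   # fold remainder into last frame
        _ensure_capacity(state, config, p_nuc, chunk)
        if buf.f_fil.shape[0] != state.fil_x.shape[0]:
            buf.f_fil = np.zeros_like(state.fil_x)
        if log_events and buf.stats[_kernel.S_NEV] > 0.9 * len(buf.ev_time):
            buf.grow_events()
        n_fil, t = _kernel.run_steps(
            chunk, state.time, dt, config.kT,
            config.R, config.k_wall, config.k_rep, config.k_seg,
            config.k_link, config.k_motor, config.kappa,
            config.segment_length, config.gamma_fil,
            config.v_motor, config.f_stall, config.k_on, config.k_off,
            config.r_capture, config.allow_self_binding,
            config.bell_unbinding, config.bell_force_scale,
            p_nuc, config.initial_length, config.growth_speed,
            config.max_length, p_del,
            config.mode == "attached", config.isotropic_nucleation,
            state.org_pos, state.org_rad, state.org_gamma,
            state.org_nucleates,
            state.motor_host, state.motor_offset, state.motor_fil,
            state.motor_s,
            state.fil_active, state.fil_nv, state.fil_x, state.fil_rest,
            state.fil_length, state.fil_host, state.fil_anchor,
            state.fil_origin, state.fil_age, state.n_fil,
            rng, buf.stats, log_events,
            buf.ev_time, buf.ev_kind, buf.ev_id1, buf.ev_id2,
            buf.f_org, buf.f_fil,
        )
        state.n_fil = int(n_fil)
        state.time = float(t)
        if buf.stats[_kernel.S_ERROR]:
            _raise_nonfinite(state, int(buf.stats[_kernel.S_ERROR]))
        if buf.stats[_kernel.S_OVERFLOW]:
            raise RuntimeError("filament capacity exhausted mid-chunk")
        done += chunk
        times.append(state.time)
        frames.append(state.org_pos.copy())
        if record_filaments:
            fil_frames.append(_snapshot_filaments(state))
        if record_motors:
            motor_frames.append(_snapshot_motors(state))

    return Trajectory(
        config=config,
        times=np.asarray(times),
        org_xy=np.asarray(frames),
        events=buf.event_log(),
        final_state=state,
        fil_frames=fil_frames,
        motor_frames=motor_frames,
    )


def _ensure_capacity(
    state: SystemState, config: SimConfig, p_nuc: float, steps: int
) -> None:
    expected = config.n_organelles * p_nuc * steps
    margin = int(expected + 10.0 * math.sqrt(expected + 1.0) + 64)
    state.ensure_filament_capacity(state.n_fil + margin)


def _snapshot_filaments(state: SystemState):
    rows = []
    for f in state.active_filaments:
        nv = int(state.fil_nv[f])
        rows.append(
            (int(f), state.fil_x[f, :nv].copy())
        )
    return rows


def _snapshot_motors(state: SystemState):
    return (
        state.motor_fil.copy(),
        state.motor_s.copy(),
    )
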