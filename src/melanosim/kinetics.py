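"""Stochastic per-step events: filament birth/growth/death, motor cycling.

Thin wrappers over the compiled phase kernels so each event class can be
driven and audited in isolation.  ``run_simulation`` executes the same
kernels in the fixed order

    turnover -> nucleation -> growth -> unbind -> bind -> walk -> mechanics

Event bookkeeping: every Bernoulli trial increments an exposure counter
immediately before its draw, so realized event counts are exactly
Binomial(exposure, p) — the property the rate tests check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from ._kernel import (
    EV_BIND,
    EV_DELETE,
    EV_ENDDET,
    EV_NUCLEATE,
    EV_UNBIND,
    N_STATS,
)
from .config import SimConfig
from .state import SystemState

__all__ = [
    "EventLog",
    "nucleate_filaments",
    "grow_filaments",
    "turnover_filaments",
    "motor_bind",
    "motor_walk",
    "motor_unbind",
]

EVENT_NAMES = {
    EV_NUCLEATE: "nucleate",
    EV_DELETE: "delete",
    EV_BIND: "bind",
    EV_UNBIND: "unbind",
    EV_ENDDET: "end_detach",
}


@dataclass
class EventLog:
    """Audit trail of kinetic events plus exposure counters."""

    time: np.ndarray
    kind: np.ndarray
    primary_id: np.ndarray
    secondary_id: np.ndarray
    counts: dict[str, int]
    exposures: dict[str, int]
    polarity_violations: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "event": [EVENT_NAMES[k] for k in self.kind],
                "primary_id": self.primary_id,
                "secondary_id": self.secondary_id,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Buffers:
    """Reusable stats/event/force buffers for kernel calls."""

    def __init__(self, state: SystemState, capacity: int = 0) -> None:
        self.stats = np.zeros(N_STATS, dtype=np.int64)
        self.ev_time = np.zeros(capacity, dtype=np.float64)
        self.ev_kind = np.zeros(capacity, dtype=np.int64)
        self.ev_id1 = np.zeros(capacity, dtype=np.int64)
        self.ev_id2 = np.zeros(capacity, dtype=np.int64)
        self.log = capacity > 0
        self.f_org = np.zeros_like(state.org_pos)
        self.f_fil = np.zeros_like(state.fil_x)

    def grow_events(self) -> None:
        for name in ("ev_time", "ev_kind", "ev_id1", "ev_id2"):
            a = getattr(self, name)
            setattr(self, name, np.concatenate([a, np.zeros_like(a)]))

    def event_log(self) -> EventLog:
        n = int(self.stats[_kernel.S_NEV])
        s = self.stats
        return EventLog(
            time=self.ev_time[:n].copy(),
            kind=self.ev_kind[:n].copy(),
            primary_id=self.ev_id1[:n].copy(),
            secondary_id=self.ev_id2[:n].copy(),
            counts={
                "nucleate": int(s[_kernel.S_NUC]),
                "delete": int(s[_kernel.S_DEL]),
                "bind": int(s[_kernel.S_BIND]),
                "unbind": int(s[_kernel.S_UNBIND]),
                "end_detach": int(s[_kernel.S_ENDDET]),
            },
            exposures={
                "nucleate": int(s[_kernel.S_EXPO_NUC]),
                "delete": int(s[_kernel.S_EXPO_FIL]),
                "bind": int(s[_kernel.S_EXPO_FREE]),
                "unbind": int(s[_kernel.S_EXPO_BOUND]),
            },
            polarity_violations=int(s[_kernel.S_POLARITY]),
        )


def _no_events():
    z = np.zeros(0)
    zi = np.zeros(0, dtype=np.int64)
    return z, zi, zi, zi


def nucleate_filaments(
    state: SystemState, config: SimConfig, rng: np.random.Generator
) -> int:
    """One nucleation sweep; returns the number of filaments created.

    Each nucleation-enabled organelle spawns a filament with probability
    1 - exp(-r_nuc*dt): pointed end at a uniform surface point, directed
    along the outward normal (or isotropically if configured).  In
    attached mode the pointed end is tethered to that surface point; in
    detached mode the filament is created identically but free.
    """
    p = 1.0 - math.exp(-config.nucleation_rate * config.dt)
    if p <= 0.0:
        return 0
    state.ensure_filament_capacity(state.n_fil + state.n_organelles)
    stats = np.zeros(N_STATS, dtype=np.int64)
    evt, evk, ev1, ev2 = _no_events()
    state.n_fil = _kernel.nucleation_phase(
        state.time, p, config.initial_length,
        config.mode == "attached", config.isotropic_nucleation,
        state.org_pos, state.org_rad, state.org_nucleates,
        state.fil_active, state.fil_nv, state.fil_x, state.fil_rest,
        state.fil_length, state.fil_host, state.fil_anchor,
        state.fil_origin, state.fil_age, state.n_fil,
        rng, stats, False, evt, evk, ev1, ev2,
    )
    return int(stats[_kernel.S_NUC])


def grow_filaments(state: SystemState, config: SimConfig) -> None:
    """Barbed-end elongation by v_g*dt (capped at L_max), with vertex
    insertion once the end segment exceeds 1.5*s0."""
    _kernel.growth_phase(
        config.dt, config.growth_speed, config.max_length,
        config.segment_length,
        state.fil_active, state.fil_nv, state.fil_x, state.fil_rest,
        state.fil_length, state.fil_age, state.n_fil,
    )


def turnover_filaments(
    state: SystemState, config: SimConfig, rng: np.random.Generator
) -> int:
    """Whole-filament stochastic deletion; bound motors are released."""
    if not math.isfinite(config.filament_lifetime):
        return 0
    p = 1.0 - math.exp(-config.dt / config.filament_lifetime)
    stats = np.zeros(N_STATS, dtype=np.int64)
    evt, evk, ev1, ev2 = _no_events()
    _kernel.turnover_phase(
        state.time, p, state.fil_active, state.fil_host, state.n_fil,
        state.motor_fil, state.motor_s,
        rng, stats, False, evt, evk, ev1, ev2,
    )
    return int(stats[_kernel.S_DEL])


def motor_bind(
    state: SystemState, config: SimConfig, rng: np.random.Generator
) -> int:
    """Free motors bind the closest filament point within r_capture."""
    stats = np.zeros(N_STATS, dtype=np.int64)
    evt, evk, ev1, ev2 = _no_events()
    _kernel.bind_phase(
        state.time, config.dt, config.k_on, config.r_capture,
        config.allow_self_binding,
        state.org_pos, state.motor_host, state.motor_offset,
        state.motor_fil, state.motor_s,
        state.fil_active, state.fil_nv, state.fil_x, state.fil_rest,
        state.fil_origin, state.n_fil,
        rng, stats, False, evt, evk, ev1, ev2,
    )
    return int(stats[_kernel.S_BIND])


def motor_walk(state: SystemState, config: SimConfig) -> int:
    """Advance bound motors toward barbed ends (linear force-velocity);
    returns the number of end detachments."""
    stats = np.zeros(N_STATS, dtype=np.int64)
    evt, evk, ev1, ev2 = _no_events()
    _kernel.walk_phase(
        state.time, config.dt, config.v_motor, config.f_stall,
        config.k_motor,
        state.org_pos, state.motor_host, state.motor_offset,
        state.motor_fil, state.motor_s,
        state.fil_nv, state.fil_x, state.fil_rest, state.fil_length,
        stats, False, evt, evk, ev1, ev2,
    )
    return int(stats[_kernel.S_ENDDET])


def motor_unbind(
    state: SystemState, config: SimConfig, rng: np.random.Generator
) -> int:
    """Constant-rate (or optional Bell-law) motor release."""
    stats = np.zeros(N_STATS, dtype=np.int64)
    evt, evk, ev1, ev2 = _no_events()
    _kernel.unbind_phase(
        state.time, config.dt, config.k_off, config.bell_unbinding,
        config.bell_force_scale, config.k_motor,
        state.org_pos, state.motor_host, state.motor_offset,
        state.motor_fil, state.motor_s,
        state.fil_nv, state.fil_x, state.fil_rest,
        rng, stats, False, evt, evk, ev1, ev2,
    )
    return int(stats[_kernel.S_UNBIND])
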