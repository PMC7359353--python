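"""Force laws on user-level objects.

These wrap the same compiled kernels the integrator runs, so what the
tests probe here is exactly what a simulation exerts.  Every pairwise
interaction returns an equal-and-opposite pair (momentum conservation is
a tested invariant).
"""

from __future__ import annotations

import logging

import numpy as np

from . import _kernel
from .state import FREE, CellSpace, FilamentState, MotorState, SystemState

__all__ = [
    "pair_repulsion",
    "confinement_force",
    "filament_internal_forces",
    "filament_energy",
    "link_force",
    "motor_force",
]

log = logging.getLogger(__name__)


def pair_repulsion(posA, posB, radA: float, radB: float, k_rep: float):
    """Soft-disk steric force pair; zero once the disks separate.

    Overlapping disks repel with magnitude ``k_rep * overlap`` along the
    centre line.  Coincident centres fall back to the +x axis (logged).
    """
    posA = np.asarray(posA, dtype=float)
    posB = np.asarray(posB, dtype=float)
    if not (np.all(np.isfinite(posA)) and np.all(np.isfinite(posB))):
        raise ValueError("positions must be finite")
    if radA <= 0 or radB <= 0 or k_rep <= 0:
        raise ValueError("radii and k_rep must be > 0")
    if np.linalg.norm(posA - posB) < 1e-12:
        log.warning("coincident organelle centres; repulsion along +x")
    fx, fy = _kernel.pair_repulsion_kernel(
        posA[0], posA[1], posB[0], posB[1], radA, radB, k_rep
    )
    fA = np.array([fx, fy])
    return fA, -fA


def confinement_force(pos, rad: float, cell: CellSpace):
    """Inward radial restoring force once ``|pos| + rad`` exceeds R."""
    pos = np.asarray(pos, dtype=float)
    fx, fy = _kernel.confinement_kernel(
        pos[0], pos[1], rad, cell.R, cell.k_wall
    )
    return np.array([fx, fy])


def filament_energy(
    vertices, rest_lengths, s0: float, kappa: float, k_seg: float
) -> float:
    """Stretch + bending energy of a discretised filament.

    E = sum_i k_seg/2 (l_i - rest_i)^2 + (kappa/s0) sum_j (1 - cos th_j)

    Independent of the force kernel; the test suite differentiates this
    numerically to validate the analytic forces.
    """
    x = np.asarray(vertices, dtype=float)
    rest = np.asarray(rest_lengths, dtype=float)
    seg = np.diff(x, axis=0)
    ln = np.linalg.norm(seg, axis=1)
    e = 0.5 * k_seg * np.sum((ln - rest) ** 2)
    if len(x) > 2 and kappa > 0:
        t = seg / ln[:, None]
        cos = np.sum(t[:-1] * t[1:], axis=1)
        e += (kappa / s0) * np.sum(1.0 - cos)
    return float(e)


def filament_internal_forces(
    filament: FilamentState, s0: float, kappa: float, k_seg: float
) -> np.ndarray:
    """Per-vertex stretch and bending forces (sum is zero)."""
    x = np.ascontiguousarray(filament.vertices, dtype=float)
    nv = len(x)
    if nv < 2:
        raise ValueError("a filament needs at least 2 vertices")
    f = np.zeros_like(x)
    bad = _kernel.filament_forces_kernel(
        nv, x, np.ascontiguousarray(filament.rest_lengths, dtype=float),
        s0, kappa, k_seg, f,
    )
    if bad:
        raise ValueError("degenerate zero-length segment: corrupted state")
    return f


def link_force(filament: FilamentState, organelle_pos, k_link: float):
    """Pointed-end tether spring; returns (force on vertex 0, reaction)."""
    if filament.host == FREE or filament.anchor_offset is None:
        raise ValueError("filament is not attached")
    anchor = np.asarray(organelle_pos, dtype=float) + filament.anchor_offset
    d = anchor - filament.vertices[0]
    f0 = k_link * d
    return f0, -f0


def motor_force(
    motor: MotorState, filament: FilamentState, organelle_pos,
    k_motor: float,
):
    """Motor spring between anchor and the arc point on the track.

    Returns ``(force_on_organelle, per_vertex_forces_on_filament)``; the
    filament side is split linearly between the two vertices bounding
    the arc coordinate, and action-reaction holds exactly.
    """
    if not motor.bound:
        raise ValueError("motor is not bound")
    s = motor.arc_s
    if s < -1e-12 or s > filament.length + 1e-12:
        raise ValueError(
            f"arc coordinate {s} outside [0, {filament.length}]: "
            "corrupted state"
        )
    nv = len(filament.vertices)
    j, frac = _kernel.locate_arc(
        s, nv, np.ascontiguousarray(filament.rest_lengths, dtype=float)
    )
    track = (1 - frac) * filament.vertices[j] + frac * filament.vertices[j + 1]
    anchor = np.asarray(organelle_pos, dtype=float) + motor.anchor_offset
    f_fil_point = k_motor * (anchor - track)
    per_vertex = np.zeros((nv, 2))
    per_vertex[j] = (1 - frac) * f_fil_point
    per_vertex[j + 1] += frac * f_fil_point
    return -f_fil_point, per_vertex


def system_forces(state: SystemState, config) -> tuple[np.ndarray, np.ndarray]:
    """Assemble all forces on a full state (as the integrator does)."""
    f_org = np.zeros_like(state.org_pos)
    f_fil = np.zeros_like(state.fil_x)
    err = _kernel.compute_forces(
        state.org_pos, state.org_rad,
        state.motor_host, state.motor_offset, state.motor_fil, state.motor_s,
        state.fil_active, state.fil_nv, state.fil_x, state.fil_rest,
        state.fil_host, state.fil_anchor, state.n_fil,
        config.R, config.k_wall, config.k_rep, config.k_seg,
        config.k_link, config.k_motor, config.kappa, config.segment_length,
        f_org, f_fil,
    )
    if err:
        raise ValueError(f"degenerate filament segment (filament {err - 1})")
    return f_org, f_fil
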