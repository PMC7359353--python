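"""Mechanical state of one simulated cell.

The state is stored as flat numpy arrays (structure-of-arrays) so the
numba integrator can work on it directly; small dataclass views
(:class:`OrganelleState`, :class:`FilamentState`, :class:`MotorState`)
are built on demand for inspection and testing.

Conventions
-----------
* Filament vertices are ordered pointed end (index 0) to barbed end.
* ``fil_rest`` holds per-segment rest (contour) lengths; the contour
  length ``fil_length`` is their running sum, maintained exactly by the
  growth bookkeeping.
* Motor arc coordinates are contour coordinates measured from the
  pointed end, so barbed-end-directed walking is monotone by
  construction.
* Entity ids are array indices; filament slots are never reused within
  a run, so ascending index equals ascending id (creation order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

__all__ = [
    "CellSpace",
    "OrganelleState",
    "FilamentState",
    "MotorState",
    "SystemState",
]

FREE = -1  # sentinel for "no filament" / "no host organelle"


@dataclass(frozen=True)
class CellSpace:
    """Circular cell of radius ``R`` with a soft confining wall."""

    R: float
    k_wall: float = 30.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("cell radius must be > 0")
        if self.k_wall < 0:
            raise ValueError("k_wall must be >= 0")


@dataclass(frozen=True)
class OrganelleState:
    id: int
    position: np.ndarray
    radius: float
    gamma: float
    motor_anchor_offsets: np.ndarray  # (M, 2), each of magnitude ``radius``
    nucleation_enabled: bool = True


@dataclass(frozen=True)
class FilamentState:
    id: int
    vertices: np.ndarray           # (nv, 2); index 0 = pointed end
    rest_lengths: np.ndarray       # (nv-1,)
    length: float                  # contour length (sum of rest lengths)
    host: int = FREE               # organelle id of pointed-end tether
    anchor_offset: Optional[np.ndarray] = None
    age: float = 0.0


@dataclass(frozen=True)
class MotorState:
    id: int
    host: int
    anchor_offset: np.ndarray
    bound_filament: int = FREE
    arc_s: float = 0.0

    @property
    def bound(self) -> bool:
        return self.bound_filament != FREE


class SystemState:
    """Full mechanical state at one time point (array-backed)."""

    def __init__(
        self,
        cell: CellSpace,
        org_pos: np.ndarray,
        org_rad: np.ndarray,
        org_gamma: np.ndarray,
        motor_host: np.ndarray,
        motor_offset: np.ndarray,
        *,
        org_nucleates: Optional[np.ndarray] = None,
        time: float = 0.0,
        fil_capacity: int = 64,
        max_vertices: int = 9,
    ) -> None:
        n = len(org_pos)
        self.cell = cell
        self.time = float(time)
        self.org_pos = np.ascontiguousarray(org_pos, dtype=np.float64)
        self.org_rad = np.ascontiguousarray(org_rad, dtype=np.float64)
        self.org_gamma = np.ascontiguousarray(org_gamma, dtype=np.float64)
        if org_nucleates is None:
            org_nucleates = np.ones(n, dtype=np.uint8)
        self.org_nucleates = np.ascontiguousarray(org_nucleates, dtype=np.uint8)
        self.motor_host = np.ascontiguousarray(motor_host, dtype=np.int64)
        self.motor_offset = np.ascontiguousarray(motor_offset, dtype=np.float64)
        nm = len(self.motor_host)
        self.motor_fil = np.full(nm, FREE, dtype=np.int64)
        self.motor_s = np.zeros(nm, dtype=np.float64)

        self.max_vertices = int(max_vertices)
        self._alloc_filaments(int(fil_capacity))
        self.n_fil = 0  # slots ever used (== next filament id)
        self._validate()

    # ------------------------------------------------------------------
    def _alloc_filaments(self, capacity: int) -> None:
        v = self.max_vertices
        self.fil_active = np.zeros(capacity, dtype=np.uint8)
        self.fil_nv = np.zeros(capacity, dtype=np.int64)
        self.fil_x = np.zeros((capacity, v, 2), dtype=np.float64)
        self.fil_rest = np.zeros((capacity, v - 1), dtype=np.float64)
        self.fil_length = np.zeros(capacity, dtype=np.float64)
        self.fil_host = np.full(capacity, FREE, dtype=np.int64)
        self.fil_anchor = np.zeros((capacity, 2), dtype=np.float64)
        self.fil_origin = np.full(capacity, FREE, dtype=np.int64)
        self.fil_age = np.zeros(capacity, dtype=np.float64)

    @property
    def fil_capacity(self) -> int:
        return len(self.fil_active)

    def ensure_filament_capacity(self, needed: int) -> None:
        """Grow filament arrays (never shrinks; ids are slot indices)."""
        cap = self.fil_capacity
        if needed <= cap:
            return
        new_cap = max(needed, 2 * cap)
        old = (self.fil_active, self.fil_nv, self.fil_x, self.fil_rest,
               self.fil_length, self.fil_host, self.fil_anchor,
               self.fil_origin, self.fil_age)
        self._alloc_filaments(new_cap)
        self.fil_host[:] = FREE
        for new, prev in zip(
            (self.fil_active, self.fil_nv, self.fil_x, self.fil_rest,
             self.fil_length, self.fil_host, self.fil_anchor,
             self.fil_origin, self.fil_age),
            old,
        ):
            new[: len(prev)] = prev

    # ------------------------------------------------------------------
    @property
    def n_organelles(self) -> int:
        return len(self.org_pos)

    @property
    def n_motors(self) -> int:
        return len(self.motor_host)

    @property
    def active_filaments(self) -> np.ndarray:
        return np.flatnonzero(self.fil_active[: self.n_fil])

    def organelle(self, i: int) -> OrganelleState:
        sel = self.motor_host == i
        return OrganelleState(
            id=i,
            position=self.org_pos[i].copy(),
            radius=float(self.org_rad[i]),
            gamma=float(self.org_gamma[i]),
            motor_anchor_offsets=self.motor_offset[sel].copy(),
            nucleation_enabled=bool(self.org_nucleates[i]),
        )

    def filament(self, f: int) -> FilamentState:
        if not (0 <= f < self.n_fil and self.fil_active[f]):
            raise KeyError(f"no active filament with id {f}")
        nv = int(self.fil_nv[f])
        host = int(self.fil_host[f])
        return FilamentState(
            id=f,
            vertices=self.fil_x[f, :nv].copy(),
            rest_lengths=self.fil_rest[f, : nv - 1].copy(),
            length=float(self.fil_length[f]),
            host=host,
            anchor_offset=self.fil_anchor[f].copy() if host != FREE else None,
            age=float(self.fil_age[f]),
        )

    def motor(self, m: int) -> MotorState:
        return MotorState(
            id=m,
            host=int(self.motor_host[m]),
            anchor_offset=self.motor_offset[m].copy(),
            bound_filament=int(self.motor_fil[m]),
            arc_s=float(self.motor_s[m]),
        )

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if np.any(self.org_rad <= 0):
            raise ValueError("organelle radii must be > 0")
        if np.any(self.org_gamma <= 0):
            raise ValueError("organelle drags must be > 0")
        r = np.linalg.norm(self.org_pos, axis=1)
        tol = 1e-9
        if np.any(r + self.org_rad > self.cell.R + tol) and self.cell.k_wall > 0:
            raise ValueError("organelle outside the cell at construction")
        if len(self.motor_host) and (
            self.motor_host.min() < 0
            or self.motor_host.max() >= self.n_organelles
        ):
            raise ValueError("motor host id out of range")

    def check_integrity(self) -> None:
        """Referential-integrity assertions (cheap; used by tests)."""
        for m in range(self.n_motors):
            f = int(self.motor_fil[m])
            if f != FREE:
                assert 0 <= f < self.n_fil and self.fil_active[f], (
                    f"motor {m} references dead filament {f}"
                )
                assert -1e-9 <= self.motor_s[m] <= self.fil_length[f] + 1e-9
        for f in self.active_filaments:
            h = int(self.fil_host[f])
            if h != FREE:
                assert 0 <= h < self.n_organelles

    # ------------------------------------------------------------------
    # lossless serialization (round-trips bit-exactly through JSON)
    def to_dict(self) -> dict[str, Any]:
        def arr(a: np.ndarray) -> list:
            return a.tolist()

        nf = self.n_fil
        return {
            "time": self.time,
            "cell": {"R": self.cell.R, "k_wall": self.cell.k_wall},
            "max_vertices": self.max_vertices,
            "n_fil": nf,
            "org_pos": arr(self.org_pos),
            "org_rad": arr(self.org_rad),
            "org_gamma": arr(self.org_gamma),
            "org_nucleates": arr(self.org_nucleates),
            "motor_host": arr(self.motor_host),
            "motor_offset": arr(self.motor_offset),
            "motor_fil": arr(self.motor_fil),
            "motor_s": arr(self.motor_s),
            "fil_active": arr(self.fil_active[:nf]),
            "fil_nv": arr(self.fil_nv[:nf]),
            "fil_x": arr(self.fil_x[:nf]),
            "fil_rest": arr(self.fil_rest[:nf]),
            "fil_length": arr(self.fil_length[:nf]),
            "fil_host": arr(self.fil_host[:nf]),
            "fil_anchor": arr(self.fil_anchor[:nf]),
            "fil_origin": arr(self.fil_origin[:nf]),
            "fil_age": arr(self.fil_age[:nf]),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SystemState":
        state = cls(
            CellSpace(**d["cell"]),
            np.asarray(d["org_pos"], dtype=np.float64).reshape(-1, 2),
            np.asarray(d["org_rad"], dtype=np.float64),
            np.asarray(d["org_gamma"], dtype=np.float64),
            np.asarray(d["motor_host"], dtype=np.int64),
            np.asarray(d["motor_offset"], dtype=np.float64).reshape(-1, 2),
            org_nucleates=np.asarray(d["org_nucleates"], dtype=np.uint8),
            time=d["time"],
            fil_capacity=max(64, d["n_fil"]),
            max_vertices=d["max_vertices"],
        )
        nf = d["n_fil"]
        state.n_fil = nf
        if nf:
            state.fil_active[:nf] = np.asarray(d["fil_active"], dtype=np.uint8)
            state.fil_nv[:nf] = np.asarray(d["fil_nv"], dtype=np.int64)
            state.fil_x[:nf] = np.asarray(d["fil_x"], dtype=np.float64)
            state.fil_rest[:nf] = np.asarray(d["fil_rest"], dtype=np.float64)
            state.fil_length[:nf] = np.asarray(d["fil_length"], dtype=np.float64)
            state.fil_host[:nf] = np.asarray(d["fil_host"], dtype=np.int64)
            state.fil_anchor[:nf] = np.asarray(d["fil_anchor"], dtype=np.float64)
            state.fil_origin[:nf] = np.asarray(d["fil_origin"], dtype=np.int64)
            state.fil_age[:nf] = np.asarray(d["fil_age"], dtype=np.float64)
        state.motor_fil[:] = np.asarray(d["motor_fil"], dtype=np.int64)
        state.motor_s[:] = np.asarray(d["motor_s"], dtype=np.float64)
        return state

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SystemState":
        return cls.from_dict(json.loads(Path(path).read_text()))
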