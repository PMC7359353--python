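"""Simulation configuration: the single source of truth for a run.

All quantities are expressed in micrometres (um), seconds (s) and
piconewtons (pN).  Thermal energy kT is therefore in pN*um
(kT ~ 0.0042 pN*um at physiological temperature).

The default parameter set describes a 2D circular melanocyte cell body of
radius ``R`` containing ``n_organelles`` melanosomes.  Each melanosome
carries membrane-anchored myosin-Va motors (``motors_per_organelle``) and
nucleates short actin filaments from its surface (``nucleation_rate``),
whose barbed ends elongate into the cytoplasm (``growth_speed``).  In
``attached`` mode the filament pointed end stays tethered to the
nucleating organelle; in ``detached`` mode filaments are released at
birth.  This mode flag is the experiment: connected networks disperse a
clustered organelle population, free filaments do so far less.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys, invalid values or unstable time steps."""


@dataclass
class SimConfig:
    # --- cell geometry ---
    R: float = 10.0                  # cell radius (um)
    k_wall: float = 30.0             # confinement stiffness (pN/um)

    # --- thermodynamics / integration ---
    kT: float = 0.0042               # thermal energy (pN*um)
    dt: float = 1e-3                 # time step (s)
    duration: float = 300.0          # total simulated time (s)
    frame_rate: float = 1.0          # output cadence (frames/s)

    # --- organelles ---
    n_organelles: int = 60
    organelle_radius: float = 0.25   # um
    gamma_org: float = 6.0 * math.pi * 0.3 * 0.25   # Stokes drag, 0.3 Pa*s (pN*s/um)
    cluster_radius: float = 3.0      # initial perinuclear cluster radius (um)

    # --- motors (myosin-Va) ---
    motors_per_organelle: int = 1    # simultaneously engaged motor linkages
    k_motor: float = 30.0            # motor spring stiffness (pN/um)
    v_motor: float = 0.5             # unloaded speed toward barbed end (um/s)
    f_stall: float = 3.0             # stall force (pN)
    k_on: float = 5.0                # binding rate when a track is in range (1/s)
    k_off: float = 0.3               # unbinding rate (1/s)
    r_capture: float = 0.1           # capture radius (um)

    # --- filaments (SPIRE-nucleated, FMN1-elongated actin) ---
    nucleation_rate: float = 0.05    # per organelle (1/s)
    initial_length: float = 0.25     # length at nucleation (um)
    growth_speed: float = 0.3        # barbed-end elongation (um/s)
    max_length: float = 3.0          # growth stops here (um)
    filament_lifetime: float = 20.0  # mean whole-filament turnover time (s)
    segment_length: float = 0.5      # bead-spring discretisation s0 (um)
    kappa: float = 0.042             # bending rigidity = Lp*kT, Lp ~ 10 um (pN*um^2)
    k_seg: float = 30.0              # stretch stiffness per segment (pN/um)
    k_link: float = 30.0             # pointed-end/organelle tether stiffness (pN/um)
    gamma_per_length: float = 0.6    # filament drag per unit length (pN*s/um^2)

    # --- interactions ---
    k_rep: float = 30.0              # organelle-organelle steric stiffness (pN/um)

    # --- mode flags ---
    mode: str = "attached"           # "attached" | "detached"
    allow_self_binding: bool = True
    isotropic_nucleation: bool = False
    bell_unbinding: bool = False
    bell_force_scale: float = 2.0    # detachment force scale for the Bell law (pN)

    # --- bookkeeping ---
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def gamma_fil(self) -> float:
        """Per-vertex filament drag (pN*s/um)."""
        return self.gamma_per_length * self.segment_length

    @property
    def stability_bound(self) -> float:
        """Largest admissible time step, 0.1 * gamma_min / k_max.

        Explicit Euler-Maruyama resolves the fastest spring relaxation
        time gamma/k only if dt is well below it.  Returns ``inf`` when
        no springs are active.
        """
        k_max = max(self.k_seg, self.k_link, self.k_motor,
                    self.k_rep, self.k_wall)
        if k_max <= 0.0:
            return math.inf
        gammas = [self.gamma_org]
        if self.nucleation_rate > 0 or self.max_length > 0:
            gammas.append(self.gamma_fil)
        return 0.1 * min(gammas) / k_max

    @property
    def max_vertices(self) -> int:
        """Upper bound on per-filament vertex count for array sizing."""
        return int(math.ceil(self.max_length / self.segment_length)) + 3

    # ------------------------------------------------------------------
    def validate(self) -> "SimConfig":
        def require(cond: bool, msg: str) -> None:
            if not cond:
                raise ConfigError(msg)

        require(self.R > 0, "R must be > 0")
        require(self.k_wall >= 0, "k_wall must be >= 0")
        require(self.kT >= 0, "kT must be >= 0")
        require(self.dt > 0, "dt must be > 0")
        require(self.duration >= 0, "duration must be >= 0")
        require(self.frame_rate > 0, "frame_rate must be > 0")
        require(self.n_organelles >= 0, "n_organelles must be >= 0")
        require(self.organelle_radius > 0, "organelle_radius must be > 0")
        require(self.gamma_org > 0, "gamma_org must be > 0")
        require(0 < self.cluster_radius < self.R,
                "cluster_radius must lie in (0, R)")
        require(self.motors_per_organelle >= 0,
                "motors_per_organelle must be >= 0")
        for name in ("k_motor", "v_motor", "f_stall", "k_on", "k_off",
                     "r_capture", "nucleation_rate", "growth_speed",
                     "k_seg", "k_link", "k_rep", "kappa"):
            require(getattr(self, name) >= 0, f"{name} must be >= 0")
        require(self.initial_length > 0, "initial_length must be > 0")
        require(self.max_length >= self.initial_length,
                "max_length must be >= initial_length")
        require(self.filament_lifetime > 0,
                "filament_lifetime must be > 0 (use math.inf to disable)")
        require(self.segment_length > 0, "segment_length must be > 0")
        require(self.gamma_per_length > 0, "gamma_per_length must be > 0")
        require(self.mode in ("attached", "detached"),
                f"mode must be 'attached' or 'detached', got {self.mode!r}")
        bound = self.stability_bound
        if self.dt > bound * (1.0 + 1e-12):
            raise ConfigError(
                f"dt={self.dt:g} s exceeds the stability bound "
                f"0.1*gamma_min/k_max = {bound:g} s"
            )
        return self

    # ------------------------------------------------------------------
    def replace(self, **overrides: Any) -> "SimConfig":
        """New config with ``overrides`` applied; unknown keys raise."""
        names = {f.name for f in dataclasses.fields(self)}
        for key in overrides:
            if key not in names:
                raise ConfigError(f"unknown config key: {key!r}")
        return dataclasses.replace(self, **overrides).validate()

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # YAML/JSON cannot represent inf portably across loaders; stringify.
        for k, v in d.items():
            if isinstance(v, float) and math.isinf(v):
                d[k] = "inf"
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        clean: dict[str, Any] = {}
        for key, value in data.items():
            if key not in names:
                raise ConfigError(f"unknown config key: {key!r}")
            if value == "inf":
                value = math.inf
            clean[key] = value
        return cls(**clean).validate()


def load_config(path: str | Path) -> SimConfig:
    """Load a YAML (or TOML) config file; missing keys take defaults.

    Unknown keys are rejected with the offending name; the time-step
    stability guard runs here so an unstable dt never reaches the
    integrator.
    """
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data)}")
    return SimConfig.from_dict(data)


def save_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
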