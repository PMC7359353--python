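"""Serialization: trajectory CSV + config sidecar, run manifests, reports.

Trajectory schema (long format):

    frame, time_s, entity_type, entity_id, sub_index, x_um, y_um,
    state, bound_filament, arc_s_um

with one row per organelle (always), per filament vertex and per motor
(when recorded).  A JSON sidecar stores the fully resolved config and
seed so a run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import SimConfig
from .engine import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
    "report",
    "TrajectorySchemaError",
]

COLUMNS = [
    "frame", "time_s", "entity_type", "entity_id", "sub_index",
    "x_um", "y_um", "state", "bound_filament", "arc_s_um",
]

FLOAT_FMT = "%.9f"


class TrajectorySchemaError(ValueError):
    pass


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write the trajectory CSV and its ``.json`` config sidecar."""
    path = Path(path)
    rows = []
    for k, t in enumerate(traj.times):
        for i in range(traj.n_organelles):
            rows.append((k, t, "organelle", i, 0,
                         traj.org_xy[k, i, 0], traj.org_xy[k, i, 1],
                         "", -1, 0.0))
        if traj.fil_frames is not None:
            for fid, verts in traj.fil_frames[k]:
                for v, (x, y) in enumerate(verts):
                    rows.append((k, t, "filament_vertex", fid, v,
                                 x, y, "", -1, 0.0))
        if traj.motor_frames is not None:
            m_fil, m_s = traj.motor_frames[k]
            for mid in range(len(m_fil)):
                bound = int(m_fil[mid])
                rows.append((k, t, "motor", mid, 0, np.nan, np.nan,
                             "bound" if bound >= 0 else "free",
                             bound, float(m_s[mid])))
    df = pd.DataFrame(rows, columns=COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"config": traj.config.to_dict(), "seed": traj.config.seed},
        indent=2, sort_keys=True,
    ))
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV (+ sidecar); validates the schema."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TrajectorySchemaError(f"cannot parse {path}: {exc}") from exc
    if list(df.columns) != COLUMNS:
        extra = set(df.columns) - set(COLUMNS)
        missing = set(COLUMNS) - set(df.columns)
        raise TrajectorySchemaError(
            f"schema mismatch in {path}: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    org = df[df["entity_type"] == "organelle"]
    if org.empty:
        raise TrajectorySchemaError(f"{path} holds no organelle rows")
    frames = np.sort(org["frame"].unique())
    n = org[org["frame"] == frames[0]]["entity_id"].nunique()
    counts = org.groupby("frame")["entity_id"].count()
    if not np.all(counts.values == n):
        bad = int(counts.index[counts.values != n][0])
        # locate the first CSV line of the offending frame (1-based, +1 header)
        line = int(np.flatnonzero(df["frame"].values == bad)[0]) + 2
        raise TrajectorySchemaError(
            f"truncated or ragged trajectory: frame {bad} is incomplete "
            f"(near line {line} of {path})"
        )
    times = org.groupby("frame")["time_s"].first().values
    xy = (
        org.sort_values(["frame", "entity_id"])[["x_um", "y_um"]]
        .values.reshape(len(frames), n, 2)
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    config = SimConfig()
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        config = SimConfig.from_dict(meta["config"])
    return Trajectory(config=config, times=times, org_xy=xy)


def sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    run_dir: str | Path,
    config: SimConfig,
    *,
    started: float,
    finished: Optional[float] = None,
) -> Path:
    """Record full provenance for a run directory."""
    run_dir = Path(run_dir)
    files = {
        p.name: sha256(p)
        for p in sorted(run_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "package_version": __version__,
        "started_unix": started,
        "finished_unix": _time.time() if finished is None else finished,
        "files": files,
    }
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def metrics_to_csv(traj: Trajectory, path: str | Path,
                   dilation: Optional[float] = None) -> Path:
    """Per-frame metrics table for a trajectory."""
    from .metrics import metrics_row
    from .state import CellSpace

    cell = CellSpace(traj.config.R, traj.config.k_wall)
    rows = [
        metrics_row(
            traj.org_xy[k], traj.config.organelle_radius, cell,
            time=traj.times[k], dilation=dilation,
        ).as_dict()
        for k in range(traj.n_frames)
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return Path(path)


def report(run_dir: str | Path, out_dir: Optional[str | Path] = None) -> dict:
    """Summarise a run (or sweep) directory: JSON summary + plots.

    Expects ``metrics.csv`` (single run) or ``replicates.csv`` (sweep)
    in ``run_dir``.  Writes ``summary.json`` and PNG time-course /
    comparison figures; returns the summary dict.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    out_dir = run_dir if out_dir is None else Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"package_version": __version__}

    metrics_path = run_dir / "metrics.csv"
    repl_path = run_dir / "replicates.csv"
    if not metrics_path.exists() and not repl_path.exists():
        raise FileNotFoundError(
            f"no metrics.csv or replicates.csv in {run_dir}"
        )

    if metrics_path.exists():
        df = pd.read_csv(metrics_path)
        summary["final"] = df.iloc[-1].to_dict()
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        axes[0].plot(df["time"], df["radial_dispersion_index"])
        axes[0].set_xlabel("time (s)")
        axes[0].set_ylabel("radial dispersion index")
        axes[1].plot(df["time"], df["pigment_area_fraction"])
        axes[1].axhline(50, ls="--", c="grey")
        axes[1].set_xlabel("time (s)")
        axes[1].set_ylabel("pigment area (% cell)")
        fig.tight_layout()
        fig.savefig(out_dir / "timecourse.png", metadata={"Software": ""})
        plt.close(fig)

    if repl_path.exists():
        df = pd.read_csv(repl_path)
        ok = df[df.get("error", "").fillna("") == ""]
        g = ok.groupby("preset", sort=False)
        summary["presets"] = {
            preset: {
                "radial_dispersion_index_mean":
                    float(sub["radial_dispersion_index"].mean()),
                "radial_dispersion_index_sd":
                    float(sub["radial_dispersion_index"].std()),
                "pigment_area_fraction_mean":
                    float(sub["pigment_area_fraction"].mean()),
                "pigment_area_fraction_sd":
                    float(sub["pigment_area_fraction"].std()),
                "labels": sub["label"].value_counts().to_dict(),
                "n": int(len(sub)),
            }
            for preset, sub in g
        }
        fig, ax = plt.subplots(figsize=(5, 3.5))
        names = list(g.groups)
        ax.bar(names,
               [summary["presets"][p]["pigment_area_fraction_mean"]
                for p in names],
               yerr=[np.nan_to_num(summary["presets"][p]
                                   ["pigment_area_fraction_sd"])
                     for p in names])
        ax.axhline(50, ls="--", c="grey")
        ax.set_ylabel("final pigment area (% cell)")
        fig.tight_layout()
        fig.savefig(out_dir / "preset_comparison.png",
                    metadata={"Software": ""})
        plt.close(fig)

    manifest = run_dir / "manifest.json"
    if manifest.exists():
        meta = json.loads(manifest.read_text())
        summary["seed"] = meta.get("seed")
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str)
    )
    return summary
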