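"""Readers, writers and report generation.

File formats are deliberately plain text:

* reflectivity curves and electron-density profiles: two-column
  whitespace or comma-separated text with optional ``#`` comment lines;
* trajectories: a documented frame format (below) plus optional
  GRO/XTC ingestion through MDAnalysis when installed;
* role maps: YAML;
* reports: one CSV per metric plus a JSON metadata sidecar recording the
  configuration, conventions and software version, so identical inputs
  reproduce identical files.

Trajectory text format, one block per frame::

    frame <time_ps> <Lx> <Ly> <Lz>
    <x> <y> <z>          # one line per particle, Å, fixed order

The particle order matches the role map, which is stored separately.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .types import ElectronDensityProfile, ReflectivityCurve, Trajectory, TopologyRoles

__all__ = [
    "load_reflectivity",
    "save_edp",
    "load_edp",
    "write_trajectory_text",
    "read_trajectory_text",
    "save_roles",
    "load_roles",
    "load_trajectory",
    "write_report",
]

log = logging.getLogger("memglass")

__version__ = "0.1.0"


def _load_columns(path) -> np.ndarray:
    try:
        data = np.loadtxt(path, comments="#")
    except ValueError:
        data = np.loadtxt(path, comments="#", delimiter=",")
    if data.size == 0:
        raise ValueError(f"empty file: {path}")
    return np.atleast_2d(data)


def load_reflectivity(path) -> ReflectivityCurve:
    """Read a two-column (q_z [Å⁻¹], intensity) reflectivity file.

    ``#`` comment lines are skipped; rows out of q order are sorted with
    a warning.
    """
    data = _load_columns(path)
    if data.shape[1] < 2:
        raise ValueError("reflectivity file needs two columns (q_z, intensity)")
    q, y = data[:, 0], data[:, 1]
    if np.any(np.diff(q) <= 0):
        log.warning("reflectivity q_z not sorted; sorting rows of %s", path)
        order = np.argsort(q)
        q, y = q[order], y[order]
        keep = np.concatenate([[True], np.diff(q) > 0])
        q, y = q[keep], y[keep]
    return ReflectivityCurve(q_z=q, intensity=y)


def save_edp(edp: ElectronDensityProfile, path) -> None:
    header = f"electron density profile, component={edp.component_label}\nz_A rho"
    np.savetxt(path, np.column_stack([edp.z, edp.rho]), header=header)


def load_edp(path, component_label: str = "whole-membrane") -> ElectronDensityProfile:
    data = _load_columns(path)
    return ElectronDensityProfile(z=data[:, 0], rho=data[:, 1], component_label=component_label)


def write_trajectory_text(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("# memglass trajectory: frame <t_ps> <Lx> <Ly> <Lz>; then x y z per particle (Å)\n")
        for f in range(traj.n_frames):
            t = traj.times[f]
            bx, by, bz = traj.boxes[f]
            fh.write(f"frame {t:.6f} {bx:.6f} {by:.6f} {bz:.6f}\n")
            np.savetxt(fh, traj.coords[f], fmt="%.6f")


def read_trajectory_text(path) -> Trajectory:
    times, boxes, frames = [], [], []
    current: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("frame"):
                if current:
                    frames.append(np.asarray(current))
                    current = []
                parts = line.split()
                times.append(float(parts[1]))
                boxes.append([float(p) for p in parts[2:5]])
            else:
                current.append([float(p) for p in line.split()])
    if current:
        frames.append(np.asarray(current))
    if not frames:
        raise ValueError(f"no frames in {path}")
    return Trajectory(times=np.asarray(times), boxes=np.asarray(boxes),
                      coords=np.stack(frames))


def save_roles(roles: TopologyRoles, path) -> None:
    doc = {
        "molecule_id": roles.molecule_id.tolist(),
        "molecule_type": [str(x) for x in roles.molecule_type],
        "role": [str(x) for x in roles.role],
        "electron_weight": roles.electron_weight.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_roles(path) -> TopologyRoles:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    roles = TopologyRoles(
        molecule_id=np.asarray(doc["molecule_id"]),
        molecule_type=np.asarray(doc["molecule_type"], dtype=object),
        role=np.asarray(doc["role"], dtype=object),
        electron_weight=np.asarray(doc["electron_weight"]),
    )
    roles.validate()
    return roles


def load_trajectory(path, roles_path) -> Tuple[Trajectory, TopologyRoles]:
    """Load a trajectory (text format, or GRO/XTC via MDAnalysis) + roles.

    Standard nm-based formats are converted to Å/ps on ingestion.  The
    particle count must match the role map; role invariants (one
    phosphate per lipid, electron weights) are validated.
    """
    path = Path(path)
    roles = load_roles(roles_path)
    if path.suffix in (".txt", ".traj", ""):
        traj = read_trajectory_text(path)
    else:
        try:
            import MDAnalysis as mda
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ValueError(
                f"format {path.suffix!r} requires MDAnalysis (install memglass[md])"
            ) from exc
        u = mda.Universe(str(path))
        times, boxes, coords = [], [], []
        for ts in u.trajectory:
            times.append(ts.time)  # MDAnalysis reports ps
            boxes.append(ts.dimensions[:3])  # Å
            coords.append(ts.positions.copy())  # Å
        traj = Trajectory(times=np.asarray(times), boxes=np.asarray(boxes),
                          coords=np.stack(coords))
    if traj.n_particles != roles.n_particles:
        raise ValueError(
            f"particle count mismatch: trajectory has {traj.n_particles}, "
            f"role map has {roles.n_particles}"
        )
    return traj, roles


def write_report(results: dict, prefix, metadata: Optional[dict] = None) -> list:
    """Write one CSV per metric plus a JSON metadata sidecar.

    ``results`` maps metric names to DataFrames (or dicts convertible to
    one-row DataFrames).  Outputs are deterministic: keys are sorted and
    no timestamps are recorded, so re-running an identical stage
    reproduces byte-identical files.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        value = results[name]
        df = value if isinstance(value, pd.DataFrame) else pd.DataFrame([value])
        out = prefix.parent / f"{prefix.name}_{name}.csv"
        df.to_csv(out, index=False, float_format="%.10g")
        written.append(out)
    sidecar = {
        "software": "memglass",
        "version": __version__,
        "metadata": metadata or {},
    }
    meta_path = prefix.parent / f"{prefix.name}_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(meta_path)
    return written
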