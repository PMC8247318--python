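"""Plain-text readers and writers, and the flat key-value configuration.

All formats are diffable text:

* window trajectory: two columns ``time_ps  z_nm`` with ``#`` metadata
  headers (``z0_nm``, ``k_umb``, ``T_K``, ``seed``), GROMACS-pull-output
  style; ``@`` decoration lines are tolerated as comments,
* topology: tab-separated per-atom table,
* frames: extended XYZ in nm with box/frame metadata on the comment line,
* PMF: three columns ``z_nm  W_kJmol  err_kJmol`` with metadata headers,
* config: flat ``namespace.key = value`` lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .molecules import MolecularFrame, TopologyLite, _TOPOLOGY_COLUMNS
from .sampling import UmbrellaWindowSpec, WindowTrajectory
from .wham import PMFProfile


class ParseError(ValueError):
    """Raised with file and line context for malformed inputs."""


# ---------------------------------------------------------------- windows

def write_window_file(path, trajectory: WindowTrajectory, extra_meta: dict | None = None) -> None:
    sp = trajectory.spec
    lines = [
        "# claybind umbrella window",
        f"# z0_nm = {sp.center!r}",
        f"# k_umb = {sp.force_constant!r}",
        f"# T_K = {sp.temperature!r}",
        f"# seed = {sp.seed}",
        f"# timestep_ps = {sp.timestep!r}",
    ]
    for k, v in (extra_meta or {}).items():
        lines.append(f"# {k} = {v}")
    t = trajectory.times
    lines.extend(f"{ti:.6f}\t{zi:.17g}" for ti, zi in zip(t, trajectory.samples))
    Path(path).write_text("\n".join(lines) + "\n")


def read_window_file(path) -> WindowTrajectory:
    """Parse a window file; metadata keys z0_nm, k_umb and T_K are required."""
    meta: dict[str, str] = {}
    times: list[float] = []
    samples: list[float] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("@"):
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{ln}: expected 'time z' columns, got {raw!r}")
        try:
            t, z = float(parts[0]), float(parts[1])
        except ValueError:
            raise ParseError(f"{path}:{ln}: non-numeric value in {raw!r}")
        if not (np.isfinite(t) and np.isfinite(z)):
            raise ParseError(f"{path}:{ln}: non-finite sample {raw!r}")
        if times and t <= times[-1]:
            raise ParseError(
                f"{path}:{ln}: time column must be strictly increasing "
                f"({t} after {times[-1]})"
            )
        times.append(t)
        samples.append(z)
    missing = {"z0_nm", "k_umb", "T_K"} - meta.keys()
    if missing:
        raise ParseError(f"{path}: missing metadata keys {sorted(missing)}")
    if len(samples) == 0:
        raise ParseError(f"{path}: no samples")
    dt = times[1] - times[0] if len(times) > 1 else float(meta.get("timestep_ps", 1.0))
    spec = UmbrellaWindowSpec(
        center=float(meta["z0_nm"]),
        force_constant=float(meta["k_umb"]),
        temperature=float(meta["T_K"]),
        seed=int(meta.get("seed", 0)),
        timestep=float(meta.get("timestep_ps", dt)),
        n_steps=len(samples),
    )
    return WindowTrajectory(spec=spec, samples=np.array(samples))


# ---------------------------------------------------------------- topology

def write_topology(path, topology: TopologyLite) -> None:
    with open(path, "w") as fh:
        fh.write(f"# net_charge = {topology.net_charge!r}\n")
        topology.atoms.to_csv(fh, sep="\t", index=False)


def read_topology(path) -> TopologyLite:
    """Load a topology table; structural invariants are enforced on load."""
    net = 0.0
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("net_charge"):
                net = float(body.partition("=")[2])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        atoms = pd.read_csv(fh, sep="\t")
    missing = set(_TOPOLOGY_COLUMNS) - set(atoms.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return TopologyLite(atoms=atoms, net_charge=net)


# ---------------------------------------------------------------- frames

def write_frames(path, frames: Sequence[MolecularFrame], names: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{len(fr.coords)}\n")
            bx, by, bz = fr.box
            fh.write(
                f'box="{bx:.6f} {by:.6f} {bz:.6f}" frame={fr.index} '
                f"com_distance_nm={fr.com_distance:.9f}\n"
            )
            for name, (x, y, z) in zip(names, fr.coords):
                fh.write(f"{name} {x:.9f} {y:.9f} {z:.9f}\n")


def read_frames(path, topology: TopologyLite | None = None) -> list[MolecularFrame]:
    """Read an extended-XYZ trajectory (nm).  With a topology given, every
    frame's atom count must match it."""
    frames: list[MolecularFrame] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta = dict(
            part.split("=", 1) for part in comment.replace('"', " ").split() if "=" in part
        )
        if 'box="' in comment:
            box = np.array([float(v) for v in comment.split('"')[1].split()])
        else:
            box = np.zeros(3)
        coords = np.empty((n, 3))
        for j in range(n):
            ln = i + 2 + j
            if ln >= len(lines):
                raise ParseError(f"{path}: truncated frame at line {ln + 1}")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln + 1}: expected 'name x y z'")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if topology is not None and n != len(topology):
            raise ParseError(
                f"{path}: frame {len(frames)} has {n} atoms, topology {len(topology)}"
            )
        frames.append(
            MolecularFrame(
                index=int(meta.get("frame", len(frames))),
                box=box,
                coords=coords,
                com_distance=float(meta.get("com_distance_nm", np.nan)),
            )
        )
        i += 2 + n
    return frames


# ---------------------------------------------------------------- PMF

def write_pmf(path, pmf: PMFProfile, meta: dict | None = None) -> None:
    lines = [
        "# claybind PMF",
        f"# convention = {pmf.convention}",
        f"# T_K = {pmf.temperature!r}",
    ]
    for k, v in (meta or {}).items():
        lines.append(f"# {k} = {v}")
    lines.append("# z_nm\tW_kJmol\terr_kJmol")
    lines.extend(
        f"{z:.17g}\t{w:.17g}\t{e:.17g}" for z, w, e in zip(pmf.z, pmf.w, pmf.err)
    )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pmf(path) -> PMFProfile:
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float]] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("@", "#")):
            if line.startswith("#") and "=" in line:
                k, _, v = line.lstrip("#").partition("=")
                meta[k.strip()] = v.strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{ln}: expected 'z W [err]' columns")
        z, w = float(parts[0]), float(parts[1])
        e = float(parts[2]) if len(parts) > 2 else 0.0
        rows.append((z, w, e))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.array(rows)
    return PMFProfile(
        z=arr[:, 0],
        w=arr[:, 1],
        err=arr[:, 2],
        convention=meta.get("convention", "global-min"),
        temperature=float(meta.get("T_K", 300.0)),
    )


# ---------------------------------------------------------------- config

_CONFIG_DEFAULTS: dict[str, object] = {
    "preset": "slab-neutral",
    "seed": 0,
    "layout.first_center_nm": 0.3,
    "layout.spacing_nm": 0.1,
    "layout.limit_nm": 4.0,
    "window.n_steps": 100_000,
    "window.force_constant": 1000.0,
    "window.temperature_K": 300.0,
    "wham.bin_width_nm": 0.01,
    "wham.tol": 1.0e-6,
    "wham.max_iter": 100_000,
    "wham.n_boot": 16,
    "dg.area_nm2": 12.91,
    "dg.conc_M": 1.0,
    "dg.slope_tol": 1.0,
    "dg.run_length_nm": 0.3,
    "dg.min_prominence": 1.0,
    "analysis.n_frames": 400,
    "verbosity": 1,
}


@dataclass
class PipelineConfig:
    """Flat, namespaced pipeline configuration.

    Round-trips losslessly through :func:`write_config`/:func:`read_config`;
    unknown keys are rejected on read.
    """

    values: dict = field(default_factory=lambda: dict(_CONFIG_DEFAULTS))

    def __getitem__(self, key: str):
        return self.values[key]

    def __setitem__(self, key: str, value) -> None:
        if key not in _CONFIG_DEFAULTS:
            raise KeyError(f"unknown configuration key {key!r}")
        self.values[key] = value

    def hash(self) -> str:
        """Short digest identifying the configuration (logged in outputs)."""
        canon = json.dumps(self.values, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_config(path, config: PipelineConfig) -> None:
    lines = [f"{k} = {config.values[k]!r}" for k in sorted(config.values)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> PipelineConfig:
    cfg = PipelineConfig()
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{ln}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_DEFAULTS:
            raise ParseError(f"{path}:{ln}: unknown configuration key {key!r}")
        default = _CONFIG_DEFAULTS[key]
        text = value.strip().strip("'\"")
        if isinstance(default, bool):
            cfg.values[key] = text.lower() in ("1", "true", "yes")
        elif isinstance(default, int):
            cfg.values[key] = int(text)
        elif isinstance(default, float):
            cfg.values[key] = float(text)
        else:
            cfg.values[key] = text
    return cfg
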