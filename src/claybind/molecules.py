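"""Toy adsorbate/surface systems for structural analyses.

Builds a rigid, group-resolved glyphosate model (neutral C3H8NO5P or anionic
C3H7NO5P-) above a regular aluminol-like hydroxyl lattice, and generates
frame ensembles in which the adsorbate's rigid-body orientation is Boltzmann
distributed under an optional uniform electric field along z (energy
-mu.E), emulating the dipole alignment induced by the polarization of fully
periodic electrostatics.  No water, counterions or internal flexibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import E_NM_TO_DEBYE, beta

#: Recognised functional-group labels.
GROUPS = ("COOH", "PO(OH)2", "NH", "backbone", "surface-OH", "water")

_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "AL": 26.982, "SI": 28.086,
}

_TOPOLOGY_COLUMNS = [
    "id", "name", "group", "charge", "sigma", "epsilon", "donor", "acceptor", "parent",
]


class TopologyError(ValueError):
    """Raised when a topology violates its structural invariants."""


@dataclass
class TopologyLite:
    """Per-atom table: id, name, group, charge (e), LJ sigma (nm) /
    epsilon (kJ/mol), donor/acceptor flags, and for hydrogens the id of the
    parent heavy atom.  ``reference_coords`` (nm) carry the rigid internal
    geometry used by the frame generator.
    """

    atoms: pd.DataFrame
    net_charge: float = 0.0
    reference_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = set(_TOPOLOGY_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise TopologyError(f"topology table lacks columns {sorted(missing)}")
        self.atoms = self.atoms.reset_index(drop=True)
        unknown = set(self.atoms["group"]) - set(GROUPS)
        if unknown:
            raise TopologyError(f"unknown group labels {sorted(unknown)}")
        ids = set(self.atoms["id"])
        hydro = self.atoms["name"].str.upper().str.startswith("H")
        orphans = self.atoms.loc[hydro & ~self.atoms["parent"].isin(ids), "id"]
        if len(orphans):
            raise TopologyError(
                f"hydrogens {orphans.tolist()} have no parent heavy atom"
            )
        total = float(self.atoms.loc[~self.is_surface, "charge"].sum())
        if abs(total - self.net_charge) > 1e-6:
            sums = self.atoms.loc[~self.is_surface].groupby("group")["charge"].sum()
            raise TopologyError(
                f"adsorbate charge {total:+.4f} e != declared net charge "
                f"{self.net_charge:+.1f} e; group sums: {sums.round(4).to_dict()}"
            )
        if self.reference_coords is not None:
            rc = np.asarray(self.reference_coords, dtype=float)
            if rc.shape != (len(self.atoms), 3):
                raise TopologyError("reference_coords shape mismatch with atom table")
            self.reference_coords = rc

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def is_surface(self) -> pd.Series:
        return self.atoms["group"].eq("surface-OH")

    @property
    def adsorbate_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_surface.to_numpy())

    @property
    def surface_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_surface.to_numpy())

    def masses(self) -> np.ndarray:
        """Atomic masses (amu) inferred from the leading element letter(s)."""
        out = np.empty(len(self.atoms))
        for i, name in enumerate(self.atoms["name"]):
            key = name[:2].upper() if name[:2].upper() in _ELEMENT_MASS else name[0].upper()
            try:
                out[i] = _ELEMENT_MASS[key]
            except KeyError:
                raise TopologyError(f"cannot infer element of atom name {name!r}")
        return out


@dataclass(frozen=True)
class MolecularFrame:
    """One configuration: coordinates (nm) in a box, with the adsorbate's
    centre-of-mass height above the surface oxygen plane recorded."""

    index: int
    box: np.ndarray
    coords: np.ndarray
    com_distance: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "box", np.asarray(self.box, dtype=float))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))


def _glyphosate_atoms(form: str) -> tuple[list[list], np.ndarray]:
    """Hand-built rigid glyphosate-like geometry (nm) with group-resolved
    charges; each group is internally neutral except the carboxylate of the
    anion, which carries the -1 e net charge."""
    # id name group charge sigma epsilon donor acceptor parent
    # group net charges carry a -0.25/+0.25 carboxyl->phosphonic polarity
    # (plus a +0.14/-0.14 backbone/amine pair) so the molecular dipole is
    # large and roughly end-to-end, as for the real highly polar molecule
    rows = [
        # carboxylic group  HO-C(=O)-   (net -0.25)
        [0, "C1", "COOH", 0.450, 0.336, 0.41, False, False, -1],
        [1, "O1", "COOH", -0.420, 0.300, 0.65, False, True, -1],
        [2, "O2", "COOH", -0.600, 0.300, 0.65, True, True, -1],
        [3, "HO2", "COOH", 0.320, 0.000, 0.00, False, False, 2],
        # methylene a  (backbone, net +0.14 with methylene b)
        [4, "C2", "backbone", 0.070, 0.336, 0.41, False, False, -1],
        [5, "H21", "backbone", 0.000, 0.000, 0.00, False, False, 4],
        [6, "H22", "backbone", 0.000, 0.000, 0.00, False, False, 4],
        # secondary amine  (net -0.14)
        [7, "N", "NH", -0.440, 0.325, 0.71, True, True, -1],
        [8, "HN", "NH", 0.300, 0.000, 0.00, False, False, 7],
        # methylene b
        [9, "C3", "backbone", 0.070, 0.336, 0.41, False, False, -1],
        [10, "H31", "backbone", 0.000, 0.000, 0.00, False, False, 9],
        [11, "H32", "backbone", 0.000, 0.000, 0.00, False, False, 9],
        # phosphonic group  -PO(OH)2  (net +0.25)
        [12, "P", "PO(OH)2", 0.830, 0.374, 0.84, False, False, -1],
        [13, "OP1", "PO(OH)2", -0.550, 0.296, 0.88, False, True, -1],
        [14, "OP2", "PO(OH)2", -0.440, 0.300, 0.65, True, True, -1],
        [15, "HP2", "PO(OH)2", 0.410, 0.000, 0.00, False, False, 14],
        [16, "OP3", "PO(OH)2", -0.440, 0.300, 0.65, True, True, -1],
        [17, "HP3", "PO(OH)2", 0.440, 0.000, 0.00, False, False, 16],
    ]
    coords = np.array([
        [0.000, 0.000, 0.000],    # C1
        [-0.062, 0.105, 0.020],   # O1 (=O)
        [-0.055, -0.115, -0.035], # O2 (-OH)
        [-0.150, -0.105, -0.050], # HO2
        [0.150, -0.010, 0.030],   # C2
        [0.175, -0.110, 0.055],   # H21
        [0.185, 0.055, 0.115],    # H22
        [0.225, 0.040, -0.085],   # N
        [0.200, 0.135, -0.105],   # HN
        [0.372, 0.025, -0.070],   # C3
        [0.405, -0.075, -0.045],  # H31
        [0.410, 0.055, -0.165],   # H32
        [0.455, 0.130, 0.045],    # P
        [0.420, 0.275, 0.035],    # OP1 (=O)
        [0.610, 0.115, 0.020],    # OP2 (-OH)
        [0.665, 0.185, 0.065],    # HP2
        [0.435, 0.085, 0.200],    # OP3 (-OH)
        [0.500, 0.120, 0.265],    # HP3
    ])
    if form == "anion":
        # deprotonated carboxylate (net -1.0); the phosphonic group loses its
        # excess positive polarity so the total net charge is -1 e
        rows = [r for r in rows if r[1] != "HO2"]
        coords = np.delete(coords, 3, axis=0)
        anion_q = {"C1": 0.330, "O1": -0.660, "O2": -0.670,
                   "P": 0.720, "OP1": -0.600, "OP2": -0.490, "HP2": 0.430,
                   "OP3": -0.490, "HP3": 0.430}
        for r in rows:
            if r[1] in anion_q:
                r[3] = anion_q[r[1]]
            if r[1] == "O2":
                r[6] = False  # no hydroxyl hydrogen left to donate
    elif form != "neutral":
        raise ValueError(f"form must be 'neutral' or 'anion', got {form!r}")
    return rows, coords


def glyphosate_topology(form: str = "neutral", dipole_debye: float | None = 8.0):
    """Adsorbate-only topology rows and reference coordinates.

    For the neutral form the charges are uniformly rescaled (group sums stay
    zero) so the rigid molecular dipole about the centre of mass is
    ``dipole_debye`` (default 8 D, within the 7.5-9 D range where the
    field-aligned orientation peaks are observed).  The anion keeps its
    constructed charges; its -1 e net charge forbids uniform rescaling.
    """
    rows, coords = _glyphosate_atoms(form)
    df = pd.DataFrame(rows, columns=_TOPOLOGY_COLUMNS)
    if form == "neutral" and dipole_debye is not None:
        masses = np.array(
            [_ELEMENT_MASS[n[0].upper()] for n in df["name"]]
        )
        com = masses @ coords / masses.sum()
        mu = df["charge"].to_numpy() @ (coords - com) * E_NM_TO_DEBYE
        norm = float(np.linalg.norm(mu))
        df["charge"] *= dipole_debye / norm
    return df, coords


def aluminol_surface(nx: int = 10, ny: int = 10, spacing: float = 0.3,
                     oh_length: float = 0.097, first_id: int = 1000):
    """Regular hydroxyl lattice standing in for the aluminol basal face.

    Oxygens sit on a nx x ny grid at z = 0 (the surface plane), each with a
    hydrogen ``oh_length`` nm above it; oxygens act as both H-bond donors
    (through their hydrogen) and acceptors, as aluminol oxygens do.
    """
    rows, coords = [], []
    aid = first_id
    for ix in range(nx):
        for iy in range(ny):
            x, y = (ix + 0.5) * spacing, (iy + 0.5) * spacing
            rows.append([aid, "OS", "surface-OH", -0.41, 0.317, 0.65, True, True, -1])
            coords.append([x, y, 0.0])
            rows.append([aid + 1, "HS", "surface-OH", 0.41, 0.0, 0.0, False, False, aid])
            coords.append([x, y, oh_length])
            aid += 2
    return pd.DataFrame(rows, columns=_TOPOLOGY_COLUMNS), np.array(coords)


def build_system(form: str = "neutral", nx: int = 10, ny: int = 10,
                 spacing: float = 0.3, dipole_debye: float | None = 8.0) -> TopologyLite:
    """Adsorbate + surface topology with rigid reference coordinates."""
    ads_df, ads_xyz = glyphosate_topology(form, dipole_debye=dipole_debye)
    surf_df, surf_xyz = aluminol_surface(nx=nx, ny=ny, spacing=spacing)
    atoms = pd.concat([ads_df, surf_df], ignore_index=True)
    coords = np.vstack([ads_xyz, surf_xyz])
    net = -1.0 if form == "anion" else 0.0
    return TopologyLite(atoms=atoms, net_charge=net, reference_coords=coords)


def _sample_tilt(a: float, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF sample of cos(theta) from density ~ exp(a cos(theta))."""
    if abs(a) < 1e-8:
        return 2.0 * u - 1.0
    return np.log(np.exp(-a) + u * (np.exp(a) - np.exp(-a))) / a


def _rotation_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    k = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def generate_molecular_frames(
    topology: TopologyLite,
    n_frames: int,
    com_distance: float,
    field_ez: float = 0.0,
    seed: int = 0,
    temperature: float = 300.0,
    box_z: float = 6.0,
    surface_jitter: float = 0.01,
    min_clearance: float = 0.24,
    hydrogen_clearance: float = 0.14,
    max_tries: int = 5000,
) -> list[MolecularFrame]:
    """Frame ensemble with Boltzmann-distributed rigid-body orientations.

    The adsorbate is placed with its centre of mass ``com_distance`` nm above
    the surface plane at the box centre; its orientation is drawn from the
    rigid-dipole Boltzmann distribution with energy ``-mu_z * field_ez``
    (``field_ez`` in kJ mol^-1 D^-1 along +z; 0 gives isotropic tumbling, as
    in the polarization-corrected slab model).  Orientations that dip a heavy
    adsorbate atom below ``min_clearance`` nm (a hydrogen below
    ``hydrogen_clearance`` nm) above the surface oxygen plane are rejected
    and redrawn — the hard-core exclusion a thermal ensemble imposes, which
    at contact distances favours surface-parallel poses.
    Surface hydroxyl hydrogens are jittered laterally each frame; all other
    internal geometry is rigid.
    """
    if n_frames <= 0:
        raise ValueError(f"n_frames must be positive, got {n_frames}")
    if com_distance <= 0:
        raise ValueError("com_distance must be positive")
    if topology.reference_coords is None:
        raise TopologyError("topology carries no reference coordinates")
    if np.ndim(field_ez) != 0:
        raise ValueError("field must be a scalar z-component (1-D emulation only)")

    masses = topology.masses()
    ads = topology.adsorbate_index
    surf = topology.surface_index
    ref = topology.reference_coords
    m_ads = masses[ads]
    ads_local = ref[ads] - m_ads @ ref[ads] / m_ads.sum()

    q_ads = topology.atoms["charge"].to_numpy()[ads]
    mu_ref = q_ads @ ads_local * E_NM_TO_DEBYE
    mu_mag = float(np.linalg.norm(mu_ref))
    mu_hat = mu_ref / mu_mag if mu_mag > 1e-12 else np.array([0.0, 0.0, 1.0])

    surf_xyz = ref[surf]
    hydro = topology.atoms["name"].str.upper().str.startswith("H").to_numpy()[surf]
    box_xy = surf_xyz[:, :2].max(axis=0) + surf_xyz[:, :2].min(axis=0)
    box = np.array([box_xy[0], box_xy[1], box_z])
    center_xy = box_xy / 2.0

    a = beta(temperature) * mu_mag * float(field_ez)  # field energy scale in k_B T
    ads_is_h = topology.atoms["name"].str.upper().str.startswith("H").to_numpy()[ads]
    floor = np.where(ads_is_h, hydrogen_clearance, min_clearance)
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        for _ in range(max_tries):
            cos_t = float(_sample_tilt(a, rng.random()))
            phi = rng.random() * 2 * np.pi
            psi = rng.random() * 2 * np.pi
            sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
            target = np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
            spin = _rotation_from_axis_angle(mu_hat, psi)
            cross = np.cross(mu_hat, target)
            dot = float(np.clip(mu_hat @ target, -1.0, 1.0))
            if np.linalg.norm(cross) < 1e-12:
                align = np.eye(3) if dot > 0 else _rotation_from_axis_angle(
                    np.array([1.0, 0.0, 0.0]) if abs(mu_hat[0]) < 0.9 else np.array([0.0, 1.0, 0.0]),
                    np.pi,
                )
            else:
                align = _rotation_from_axis_angle(cross, np.arccos(dot))
            rot = align @ spin
            placed = ads_local @ rot.T + np.array(
                [center_xy[0], center_xy[1], com_distance]
            )
            # hard-core exclusion against the hydroxyl lattice
            if np.all(placed[:, 2] >= floor):
                break
        else:
            raise RuntimeError(
                f"no clash-free orientation found at com_distance={com_distance} nm "
                f"after {max_tries} draws; the adsorbate cannot sit this close"
            )
        coords = np.empty_like(ref)
        coords[ads] = placed
        sxyz = surf_xyz.copy()
        jit = rng.normal(scale=surface_jitter, size=(int(hydro.sum()), 2))
        sxyz[hydro, :2] += jit
        coords[surf] = sxyz
        coords[:, :2] %= box[:2]
        com = m_ads @ coords[ads] / m_ads.sum()
        frames.append(
            MolecularFrame(index=i, box=box, coords=coords, com_distance=float(com[2]))
        )
    return frames
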