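"""Frame-trajectory analyses: hydrogen bonds, dipole orientation, energies.

All pair geometry uses the minimum-image convention in x and y only; the z
direction is open, matching a slab geometry with a single surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import COULOMB, E_NM_TO_DEBYE
from .molecules import GROUPS, MolecularFrame, TopologyLite


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    A donor-H...acceptor triple counts as a hydrogen bond when the
    donor-acceptor distance is at most ``distance_cutoff`` (nm) and the
    deviation of the D-H...A angle from linearity is at most ``angle_cutoff``
    (degrees).  Defaults are the community-standard 0.35 nm / 30 deg.
    """

    distance_cutoff: float = 0.35
    angle_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angle_cutoff > 90:
            raise ValueError("angle cutoff must be <= 90 degrees")


@dataclass(frozen=True)
class HBondRecord:
    frame_index: int
    donor: int
    hydrogen: int
    acceptor: int
    donor_group: str
    acceptor_group: str
    distance: float
    angle: float


@dataclass(frozen=True)
class DipoleDistribution:
    """Normalized histogram of the adsorbate dipole z-component (Debye)."""

    edges: np.ndarray
    probabilities: np.ndarray
    com_distance: float
    model: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, float))
        object.__setattr__(self, "probabilities", np.asarray(self.probabilities, float))

    @property
    def mode(self) -> float:
        mid = 0.5 * (self.edges[:-1] + self.edges[1:])
        return float(mid[np.argmax(self.probabilities)])


@dataclass(frozen=True)
class EnergyDistribution:
    """Normalized histogram of adsorbate-surface interaction energy (kJ/mol)."""

    edges: np.ndarray
    probabilities: np.ndarray
    com_distance: float
    condition: str = ""


def _delta_xy_min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = d.copy()
    for k in (0, 1):
        d[..., k] -= box[k] * np.round(d[..., k] / box[k])
    return d


def _pair_distances(xa: np.ndarray, xb: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = xa[:, None, :] - xb[None, :, :]
    d = _delta_xy_min_image(d, box)
    return np.sqrt((d * d).sum(axis=-1))


def detect_hbonds(
    frame: MolecularFrame,
    topology: TopologyLite,
    criterion: HBondCriterion = HBondCriterion(),
) -> list[HBondRecord]:
    """All donor-H...acceptor triples satisfying the geometric criterion.

    Donor heavy atoms are those flagged ``donor`` that carry at least one
    hydrogen; acceptors are atoms flagged ``acceptor``.  Pairs within the same
    functional group are not reported (intra-group contacts are covalent
    geometry, not hydrogen bonds).
    """
    atoms = topology.atoms
    if frame.coords.shape[0] != len(atoms):
        raise ValueError(
            f"frame has {frame.coords.shape[0]} atoms, topology {len(atoms)}"
        )
    ids = atoms["id"].to_numpy()
    row_of = {int(a): i for i, a in enumerate(ids)}
    hydro_rows = np.flatnonzero(atoms["name"].str.upper().str.startswith("H"))
    donor_flag = atoms["donor"].to_numpy(dtype=bool)
    acc_rows = np.flatnonzero(atoms["acceptor"].to_numpy(dtype=bool))
    groups = atoms["group"].to_numpy()

    records: list[HBondRecord] = []
    box = frame.box
    for h_row in hydro_rows:
        d_row = row_of[int(atoms.at[h_row, "parent"])]
        if not donor_flag[d_row]:
            continue
        dvec = frame.coords[acc_rows] - frame.coords[d_row]
        dvec = _delta_xy_min_image(dvec, box)
        dist = np.sqrt((dvec * dvec).sum(axis=-1))
        hvec_d = _delta_xy_min_image(frame.coords[h_row] - frame.coords[d_row], box)
        avec_h = _delta_xy_min_image(frame.coords[acc_rows] - frame.coords[h_row], box)
        nh = np.linalg.norm(hvec_d)
        na = np.linalg.norm(avec_h, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (avec_h @ hvec_d) / (na * nh)
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = (
            (dist <= criterion.distance_cutoff)
            & (angle <= criterion.angle_cutoff)
            & (groups[acc_rows] != groups[d_row])
            & (acc_rows != d_row)
            & (acc_rows != h_row)
            & (na > 1e-9)
        )
        for j in np.flatnonzero(ok):
            a_row = acc_rows[j]
            records.append(
                HBondRecord(
                    frame_index=frame.index,
                    donor=int(ids[d_row]),
                    hydrogen=int(ids[h_row]),
                    acceptor=int(ids[a_row]),
                    donor_group=str(groups[d_row]),
                    acceptor_group=str(groups[a_row]),
                    distance=float(dist[j]),
                    angle=float(angle[j]),
                )
            )
    return records


def group_occurrence(
    records_per_frame: list[list[HBondRecord]],
    com_distances: np.ndarray,
    groups: list[str],
    distance_edges: np.ndarray,
) -> pd.DataFrame:
    """Fraction of frames in which each group forms >= 1 hydrogen bond.

    Frames are assigned to centre-of-mass-distance bins; the result is a
    (group x distance-bin) table of occurrence fractions in [0, 1].
    """
    for g in groups:
        if g not in GROUPS:
            raise ValueError(f"unknown group label {g!r}")
    com = np.asarray(com_distances, float)
    if com.size != len(records_per_frame):
        raise ValueError("one COM distance per frame is required")
    edges = np.asarray(distance_edges, float)
    which = np.digitize(com, edges) - 1
    n_bins = edges.size - 1
    counts = np.zeros((len(groups), n_bins))
    totals = np.zeros(n_bins)
    for recs, b in zip(records_per_frame, which):
        if not 0 <= b < n_bins:
            continue
        totals[b] += 1
        present = {r.donor_group for r in recs} | {r.acceptor_group for r in recs}
        for gi, g in enumerate(groups):
            counts[gi, b] += g in present
    with np.errstate(invalid="ignore"):
        frac = np.where(totals > 0, counts / totals, np.nan)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame(frac, index=groups, columns=np.round(mid, 6))


def compute_dipole(
    frame: MolecularFrame,
    topology: TopologyLite,
    selection: np.ndarray | None = None,
    origin: str = "com",
) -> np.ndarray:
    """Dipole moment (Debye) of a selection: mu = sum q_i (r_i - r_origin).

    For a net-neutral selection the result is origin independent; for charged
    selections the centre of mass is the documented gauge (``origin="com"``;
    ``origin="geometric"`` uses the unweighted centroid).
    """
    sel = topology.adsorbate_index if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    q = topology.atoms["charge"].to_numpy()[sel]
    r = frame.coords[sel]
    if origin == "com":
        m = topology.masses()[sel]
        r0 = m @ r / m.sum()
    elif origin == "geometric":
        r0 = r.mean(axis=0)
    else:
        raise ValueError(f"unknown origin convention {origin!r}")
    return (q @ (r - r0)) * E_NM_TO_DEBYE


def dipole_z_distribution(
    frames: list[MolecularFrame],
    topology: TopologyLite,
    edges: np.ndarray | None = None,
    model: str = "",
    min_frames: int = 100,
) -> DipoleDistribution:
    """Normalized histogram of the per-frame adsorbate dipole z-component."""
    if len(frames) < min_frames:
        raise ValueError(
            f"{len(frames)} frames are too few for a reported distribution "
            f"(minimum {min_frames})"
        )
    muz = np.array([compute_dipole(f, topology)[2] for f in frames])
    if edges is None:
        lim = max(10.0, np.ceil(np.abs(muz).max()))
        edges = np.arange(-lim, lim + 0.5, 0.5)
    counts, edges = np.histogram(muz, bins=edges)
    probs = counts / counts.sum()
    com = float(np.mean([f.com_distance for f in frames]))
    return DipoleDistribution(edges=edges, probabilities=probs, com_distance=com, model=model)


def interaction_energy(
    frame: MolecularFrame,
    topology: TopologyLite,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    cutoff: float = 1.4,
) -> float:
    """Pairwise non-bonded energy (kJ/mol) between two disjoint selections.

    Coulomb + Lennard-Jones with Lorentz-Berthelot combination, hard
    truncation at ``cutoff`` nm, no shift or tail corrections.
    """
    a = np.asarray(selection_a)
    b = np.asarray(selection_b)
    if np.intersect1d(a, b).size:
        raise ValueError("selections overlap")
    atoms = topology.atoms
    r = _pair_distances(frame.coords[a], frame.coords[b], frame.box)
    within = r <= cutoff
    if not within.any():
        return 0.0
    if r[within].min() < 1e-4:
        raise ValueError(
            f"steric overlap: minimum pair distance {r[within].min():.2e} nm"
        )
    qa = atoms["charge"].to_numpy()[a]
    qb = atoms["charge"].to_numpy()[b]
    sa = atoms["sigma"].to_numpy()[a]
    sb = atoms["sigma"].to_numpy()[b]
    ea = atoms["epsilon"].to_numpy()[a]
    eb = atoms["epsilon"].to_numpy()[b]
    sig = 0.5 * (sa[:, None] + sb[None, :])
    eps = np.sqrt(ea[:, None] * eb[None, :])
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        sr6 = np.where(within, (sig / r) ** 6, 0.0)
        e = np.where(
            within,
            COULOMB * qa[:, None] * qb[None, :] / r + 4.0 * eps * (sr6 * sr6 - sr6),
            0.0,
        )
    return float(e.sum())


def energy_distribution(
    frames: list[MolecularFrame],
    topology: TopologyLite,
    selection_a: np.ndarray | None = None,
    selection_b: np.ndarray | None = None,
    edges: np.ndarray | None = None,
    cutoff: float = 1.4,
    hbond_records: list[list[HBondRecord]] | None = None,
    condition_group: str | None = None,
) -> dict[str, EnergyDistribution]:
    """Per-frame interaction-energy histograms, optionally split by H-bond state.

    With ``condition_group`` set (and per-frame H-bond records supplied) two
    histograms are returned, keyed ``"bonded"``/``"unbonded"``, according to
    whether that group forms a hydrogen bond in the frame — the attribution
    logic behind multi-modal interaction-energy distributions.  Otherwise a
    single histogram is returned under the key ``"all"``.  Empty conditioning
    classes are reported with zero probabilities, not as errors.
    """
    sel_a = topology.adsorbate_index if selection_a is None else np.asarray(selection_a)
    sel_b = topology.surface_index if selection_b is None else np.asarray(selection_b)
    energies = np.array(
        [interaction_energy(f, topology, sel_a, sel_b, cutoff=cutoff) for f in frames]
    )
    if edges is None:
        lo, hi = energies.min(), energies.max()
        pad = max(1.0, 0.05 * (hi - lo))
        edges = np.linspace(lo - pad, hi + pad, 41)
    com = float(np.mean([f.com_distance for f in frames]))

    def _hist(values: np.ndarray, label: str) -> EnergyDistribution:
        counts, _ = np.histogram(values, bins=edges)
        total = counts.sum()
        probs = counts / total if total else np.zeros(len(edges) - 1)
        return EnergyDistribution(
            edges=np.asarray(edges, float), probabilities=probs,
            com_distance=com, condition=label,
        )

    if condition_group is None:
        return {"all": _hist(energies, "all")}
    if hbond_records is None or len(hbond_records) != len(frames):
        raise ValueError("conditioning requires one H-bond record list per frame")
    bonded = np.array(
        [
            any(
                condition_group in (r.donor_group, r.acceptor_group) for r in recs
            )
            for recs in hbond_records
        ]
    )
    return {
        "bonded": _hist(energies[bonded], f"{condition_group} bonded"),
        "unbonded": _hist(energies[~bonded], f"{condition_group} unbonded"),
    }
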