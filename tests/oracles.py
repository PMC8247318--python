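"""Independent brute-force oracles shared by the test suite.

Deliberately naive implementations (explicit Python loops, textbook
equations) kept separate from the library code they check.
"""

import numpy as np
import pandas as pd

from claybind.constants import KB, COULOMB
from claybind.molecules import MolecularFrame, TopologyLite, _TOPOLOGY_COLUMNS


def naive_wham(edges, counts, centers, ks, temperature, offsets=None, n_iter=60000, tol=1e-12):
    """Deliberately plain fixed-point iteration of the WHAM equations,
    written with explicit loops as an independent oracle."""
    beta = 1.0 / (KB * temperature)
    mids = [(edges[b] + edges[b + 1]) / 2.0 for b in range(len(edges) - 1)]
    dz = edges[1] - edges[0]
    nw, nb = len(centers), len(mids)
    offsets = offsets or [0.0] * nw
    n_tot = [sum(counts[i]) for i in range(nw)]
    m = [sum(counts[i][b] for i in range(nw)) for b in range(nb)]
    keep = [b for b in range(nb) if m[b] > 0]
    v = [
        [0.5 * ks[i] * (mids[b] - centers[i]) ** 2 + offsets[i] for b in range(nb)]
        for i in range(nw)
    ]
    f = [0.0] * nw
    for _ in range(n_iter):
        p = {}
        for b in keep:
            denom = sum(
                n_tot[i] * np.exp(-beta * (v[i][b] - f[i])) for i in range(nw)
            )
            p[b] = m[b] / denom
        norm = sum(p[b] * dz for b in keep)
        for b in keep:
            p[b] /= norm
        f_new = []
        for i in range(nw):
            zsum = sum(p[b] * np.exp(-beta * v[i][b]) * dz for b in keep)
            f_new.append(-np.log(zsum) / beta)
        f_new = [fi - f_new[0] for fi in f_new]
        resid = max(abs(a - b) for a, b in zip(f_new, f))
        f = f_new
        if resid < tol:
            break
    p_final = {}
    for b in keep:
        denom = sum(n_tot[i] * np.exp(-beta * (v[i][b] - f[i])) for i in range(nw))
        p_final[b] = m[b] / denom
    norm = sum(p_final[b] * dz for b in keep)
    return {b: p_final[b] / norm for b in keep}, f



def _mi_xy(d, box):
    d = np.asarray(d, float).copy()
    for k in (0, 1):
        d[k] -= box[k] * round(d[k] / box[k])
    return d


def brute_force_hbonds(frame, topology, criterion):
    """All-triples reference detector (independent, naive loops)."""
    atoms = topology.atoms
    out = set()
    for hi in range(len(atoms)):
        if not atoms.iloc[hi]["name"].upper().startswith("H"):
            continue
        parent = atoms.iloc[hi]["parent"]
        drows = atoms.index[atoms["id"] == parent].tolist()
        if not drows:
            continue
        di = drows[0]
        if not bool(atoms.iloc[di]["donor"]):
            continue
        for ai in range(len(atoms)):
            if not bool(atoms.iloc[ai]["acceptor"]):
                continue
            if ai in (di, hi):
                continue
            if atoms.iloc[ai]["group"] == atoms.iloc[di]["group"]:
                continue
            dda = _mi_xy(frame.coords[ai] - frame.coords[di], frame.box)
            dist = float(np.linalg.norm(dda))
            if dist > criterion.distance_cutoff:
                continue
            v1 = _mi_xy(frame.coords[hi] - frame.coords[di], frame.box)
            v2 = _mi_xy(frame.coords[ai] - frame.coords[hi], frame.box)
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n2 < 1e-9:
                continue
            ang = np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1, 1)))
            if ang <= criterion.angle_cutoff:
                out.add((int(atoms.iloc[di]["id"]), int(atoms.iloc[hi]["id"]),
                         int(atoms.iloc[ai]["id"])))
    return out


def brute_force_energy(frame, topology, sel_a, sel_b, cutoff=1.4):
    atoms = topology.atoms
    total = 0.0
    for i in sel_a:
        for j in sel_b:
            d = _mi_xy(frame.coords[i] - frame.coords[j], frame.box)
            r = float(np.linalg.norm(d))
            if r > cutoff:
                continue
            qi, qj = atoms.iloc[i]["charge"], atoms.iloc[j]["charge"]
            sig = 0.5 * (atoms.iloc[i]["sigma"] + atoms.iloc[j]["sigma"])
            eps = np.sqrt(atoms.iloc[i]["epsilon"] * atoms.iloc[j]["epsilon"])
            sr6 = (sig / r) ** 6
            total += COULOMB * qi * qj / r + 4 * eps * (sr6 * sr6 - sr6)
    return total


def random_frame_and_topology(rng, n_atoms=20):
    """Small random donor/acceptor soup in a periodic box."""
    rows = []
    coords = rng.uniform(0.0, 1.2, size=(n_atoms, 3))
    groups = ["COOH", "PO(OH)2", "NH", "surface-OH"]
    heavy_ids = []
    for i in range(n_atoms):
        if i % 3 == 2 and heavy_ids:  # every third atom is a hydrogen
            parent = int(rng.choice(heavy_ids))
            rows.append([i, f"H{i}", rows[parent][2], 0.2, 0.0, 0.0, False, False, parent])
            coords[i] = coords[parent] + rng.normal(scale=0.08, size=3)
        else:
            g = groups[int(rng.integers(len(groups)))]
            rows.append([i, f"O{i}", g, -0.3, 0.3, 0.5,
                         bool(rng.integers(2)), bool(rng.integers(2)), -1])
            heavy_ids.append(i)
    df = pd.DataFrame(rows, columns=_TOPOLOGY_COLUMNS)
    net = float(df.loc[df["group"] != "surface-OH", "charge"].sum())
    top = TopologyLite(atoms=df, net_charge=net)
    frame = MolecularFrame(
        index=0, box=np.array([1.2, 1.2, 5.0]), coords=coords % [1.2, 1.2, 5.0],
        com_distance=0.5,
    )
    return frame, top


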