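"""Hydrogen bonds, dipoles and pairwise energies against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from claybind import (
    HBondCriterion,
    build_system,
    compute_dipole,
    detect_hbonds,
    dipole_z_distribution,
    energy_distribution,
    generate_molecular_frames,
    group_occurrence,
    interaction_energy,
)
from claybind.constants import COULOMB, E_NM_TO_DEBYE
from claybind.molecules import MolecularFrame, TopologyLite, _TOPOLOGY_COLUMNS
from oracles import (_mi_xy, brute_force_energy, brute_force_hbonds,
                     random_frame_and_topology)


# ------------------------------------------------------------ oracles

# ------------------------------------------------------------ H-bonds

class TestHBonds:
    def test_constructed_collinear_hit(self):
        rows = [
            [0, "OD", "COOH", -0.5, 0.30, 0.6, True, False, -1],
            [1, "HD", "COOH", 0.5, 0.00, 0.0, False, False, 0],
            [2, "OA", "surface-OH", 0.0, 0.30, 0.6, False, True, -1],
        ]
        df = pd.DataFrame(rows, columns=_TOPOLOGY_COLUMNS)
        top = TopologyLite(atoms=df, net_charge=0.0)
        coords = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 0.9], [1.0, 1.0, 0.72]])
        frame = MolecularFrame(index=0, box=np.array([4.0, 4.0, 4.0]),
                               coords=coords, com_distance=1.0)
        recs = detect_hbonds(frame, top, HBondCriterion())
        assert len(recs) == 1
        assert recs[0].donor == 0 and recs[0].acceptor == 2
        assert recs[0].distance == pytest.approx(0.28, abs=1e-9)
        assert recs[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_far_adsorbate_has_no_surface_hbonds(self):
        top = build_system("neutral", nx=5, ny=5)
        frame = generate_molecular_frames(top, 1, 5.0, seed=0)[0]
        assert detect_hbonds(frame, top) == []

    def test_atom_count_mismatch_rejected(self):
        top = build_system("neutral", nx=4, ny=4)
        frame = MolecularFrame(index=0, box=np.array([2, 2, 5.0]),
                               coords=np.zeros((3, 3)), com_distance=1.0)
        with pytest.raises(ValueError, match="atoms"):
            detect_hbonds(frame, top)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        crit = HBondCriterion(distance_cutoff=0.4, angle_cutoff=45.0)
        for _ in range(25):
            frame, top = random_frame_and_topology(rng)
            got = {(r.donor, r.hydrogen, r.acceptor)
                   for r in detect_hbonds(frame, top, crit)}
            assert got == brute_force_hbonds(frame, top, crit)

    def test_invalid_criterion_rejected(self):
        with pytest.raises(ValueError):
            HBondCriterion(distance_cutoff=-0.1)
        with pytest.raises(ValueError):
            HBondCriterion(angle_cutoff=120.0)


class TestGroupOccurrence:
    def _frames_with_records(self, n_bonded):
        top = build_system("neutral", nx=4, ny=4)
        frames = generate_molecular_frames(top, 100, 0.33, seed=3)
        recs = [detect_hbonds(f, top) for f in frames]
        return frames, recs

    def test_no_records_gives_zero(self):
        occ = group_occurrence([[] for _ in range(10)], np.full(10, 0.33),
                               ["COOH"], np.array([0.3, 0.4]))
        assert float(occ.iloc[0, 0]) == 0.0

    def test_counting_fraction(self):
        from claybind.structure import HBondRecord

        rec = HBondRecord(0, 0, 1, 2, "COOH", "surface-OH", 0.3, 5.0)
        per_frame = [[rec] if i < 40 else [] for i in range(100)]
        occ = group_occurrence(per_frame, np.full(100, 0.35), ["COOH", "NH"],
                               np.array([0.3, 0.4]))
        assert float(occ.loc["COOH"].iloc[0]) == pytest.approx(0.40)
        assert float(occ.loc["NH"].iloc[0]) == 0.0

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            group_occurrence([[]], np.array([0.33]), ["carboxyl"], np.array([0.3, 0.4]))


# ------------------------------------------------------------ dipoles

class TestDipole:
    def test_zero_charges_zero_dipole(self):
        rows = [[i, "C", "backbone", 0.0, 0.3, 0.4, False, False, -1] for i in range(3)]
        df = pd.DataFrame(rows, columns=_TOPOLOGY_COLUMNS)
        top = TopologyLite(atoms=df, net_charge=0.0)
        frame = MolecularFrame(index=0, box=np.array([3, 3, 3.0]),
                               coords=np.random.default_rng(0).uniform(0, 2, (3, 3)),
                               com_distance=1.0)
        assert np.allclose(compute_dipole(frame, top, selection=np.arange(3)), 0.0)

    def test_unit_conversion_one_debye(self):
        """+-1 e separated by 0.020817 nm along z is 1.000 D."""
        rows = [
            [0, "N", "NH", 1.0, 0.3, 0.4, False, False, -1],
            [1, "O", "COOH", -1.0, 0.3, 0.4, False, False, -1],
        ]
        df = pd.DataFrame(rows, columns=_TOPOLOGY_COLUMNS)
        top = TopologyLite(atoms=df, net_charge=0.0)
        sep = 1.0 / E_NM_TO_DEBYE
        coords = np.array([[1.0, 1.0, 1.0 + sep], [1.0, 1.0, 1.0]])
        frame = MolecularFrame(index=0, box=np.array([3, 3, 3.0]),
                               coords=coords, com_distance=1.0)
        mu = compute_dipole(frame, top, selection=np.array([0, 1]))
        assert mu[2] == pytest.approx(1.000, abs=1e-9)

    def test_translation_invariance_for_neutral_selection(self):
        top = build_system("neutral", nx=4, ny=4)
        frame = generate_molecular_frames(top, 1, 0.9, seed=4)[0]
        mu1 = compute_dipole(frame, top)
        shifted = MolecularFrame(
            index=0, box=frame.box, coords=frame.coords + np.array([0.3, -0.2, 0.55]),
            com_distance=frame.com_distance + 0.55,
        )
        mu2 = compute_dipole(shifted, top)
        assert np.allclose(mu1, mu2, atol=1e-12)

    def test_distribution_normalized_and_needs_frames(self):
        top = build_system("neutral", nx=4, ny=4)
        frames = generate_molecular_frames(top, 150, 1.0, seed=5)
        dist = dipole_z_distribution(frames, top)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError, match="too few"):
            dipole_z_distribution(frames[:50], top)


# ------------------------------------------------------------ energies

class TestInteractionEnergy:
    def _pair(self, q1, q2, r, sigma=0.0, eps=0.0):
        rows = [
            [0, "C", "COOH", q1, sigma, eps, False, False, -1],
            [1, "C", "surface-OH", q2, sigma, eps, False, False, -1],
        ]
        df = pd.DataFrame(rows, columns=_TOPOLOGY_COLUMNS)
        top = TopologyLite(atoms=df, net_charge=q1)
        coords = np.array([[2.0, 2.0, 1.0], [2.0, 2.0, 1.0 + r]])
        frame = MolecularFrame(index=0, box=np.array([8.0, 8.0, 8.0]),
                               coords=coords, com_distance=1.0)
        return frame, top

    def test_beyond_cutoff_is_zero(self):
        frame, top = self._pair(1.0, 1.0, 2.0)
        assert interaction_energy(frame, top, np.array([0]), np.array([1])) == 0.0

    def test_coulomb_pair_closed_form(self):
        """Two +1 e charges at 0.5 nm: 138.935485/0.5 = +277.87 kJ/mol."""
        frame, top = self._pair(1.0, 1.0, 0.5)
        e = interaction_energy(frame, top, np.array([0]), np.array([1]))
        assert e == pytest.approx(277.87, abs=0.01)

    def test_lj_minimum_is_minus_epsilon(self):
        sigma, eps = 0.32, 0.75
        frame, top = self._pair(0.0, 0.0, 2 ** (1 / 6) * sigma, sigma=sigma, eps=eps)
        e = interaction_energy(frame, top, np.array([0]), np.array([1]))
        assert e == pytest.approx(-eps, abs=1e-12)

    def test_overlapping_selections_rejected(self):
        frame, top = self._pair(1.0, 1.0, 0.5)
        with pytest.raises(ValueError, match="overlap"):
            interaction_energy(frame, top, np.array([0, 1]), np.array([1]))

    def test_steric_overlap_rejected(self):
        frame, top = self._pair(1.0, 1.0, 1e-5)
        with pytest.raises(ValueError, match="steric"):
            interaction_energy(frame, top, np.array([0]), np.array([1]))

    def test_additivity_over_disjoint_selections(self):
        top = build_system("neutral", nx=5, ny=5)
        frame = generate_molecular_frames(top, 1, 0.4, seed=6)[0]
        a = top.adsorbate_index
        surf = top.surface_index
        b, c = surf[: len(surf) // 2], surf[len(surf) // 2 :]
        e_bc = interaction_energy(frame, top, a, surf)
        e_b = interaction_energy(frame, top, a, b)
        e_c = interaction_energy(frame, top, a, c)
        assert e_bc == pytest.approx(e_b + e_c, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_pair_sum(self, seed):
        rng = np.random.default_rng(100 + seed)
        frame, top = random_frame_and_topology(rng, n_atoms=14)
        sel_a = np.arange(0, 7)
        sel_b = np.arange(7, 14)
        got = interaction_energy(frame, top, sel_a, sel_b, cutoff=1.0)
        ref = brute_force_energy(frame, top, sel_a, sel_b, cutoff=1.0)
        assert got == pytest.approx(ref, rel=1e-12, abs=1e-9)


class TestEnergyDistribution:
    def test_noninteracting_degenerate_at_zero(self):
        top = build_system("neutral", nx=4, ny=4)
        frames = generate_molecular_frames(top, 30, 3.0, seed=7)
        dist = energy_distribution(frames, top)["all"]
        mids = 0.5 * (dist.edges[:-1] + dist.edges[1:])
        mode = mids[np.argmax(dist.probabilities)]
        assert abs(mode) < 1.5
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_conditioning_separates_constructed_modes(self):
        """Sub-ensembles constructed bonded at -90 and unbonded at -20
        kJ/mol produce separated conditional histograms."""
        from claybind.structure import EnergyDistribution, HBondRecord

        top = build_system("neutral", nx=4, ny=4)
        frames = generate_molecular_frames(top, 40, 1.0, seed=8)
        rec = HBondRecord(0, 2, 3, 1000, "COOH", "surface-OH", 0.3, 10.0)
        hbonds = [[rec] if i < 20 else [] for i in range(40)]

        # monkeypatch energies by constructing a fake per-frame energy set:
        # use explicit edges and feed energies through interaction by scaling
        energies = np.where(np.arange(40) < 20, -90.0, -20.0)

        # direct histogram check of the conditioning logic
        import claybind.structure as S

        orig = S.interaction_energy
        try:
            it = iter(energies)
            S.interaction_energy = lambda *a, **k: float(next(it))
            dists = S.energy_distribution(
                frames, top, edges=np.linspace(-120, 0, 25),
                hbond_records=hbonds, condition_group="COOH",
            )
        finally:
            S.interaction_energy = orig
        mids = 0.5 * (dists["bonded"].edges[:-1] + dists["bonded"].edges[1:])
        mode_b = mids[np.argmax(dists["bonded"].probabilities)]
        mode_u = mids[np.argmax(dists["unbonded"].probabilities)]
        assert mode_b == pytest.approx(-90.0, abs=3.0)
        assert mode_u == pytest.approx(-20.0, abs=3.0)

    def test_empty_conditioning_class_reported_not_error(self):
        top = build_system("neutral", nx=4, ny=4)
        frames = generate_molecular_frames(top, 10, 1.5, seed=9)
        dists = energy_distribution(
            frames, top, edges=np.linspace(-50, 50, 11),
            hbond_records=[[] for _ in frames], condition_group="COOH",
        )
        assert dists["bonded"].probabilities.sum() == 0.0
        assert dists["unbonded"].probabilities.sum() == pytest.approx(1.0)


# ------------------------------------------------------------ property-based

@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_hbond_detector_equals_oracle_property(seed):
    rng = np.random.default_rng(seed)
    frame, top = random_frame_and_topology(rng, n_atoms=16)
    crit = HBondCriterion(distance_cutoff=0.38, angle_cutoff=35.0)
    got = {(r.donor, r.hydrogen, r.acceptor) for r in detect_hbonds(frame, top, crit)}
    assert got == brute_force_hbonds(frame, top, crit)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), shift=st.floats(-1.0, 1.0))
def test_dipole_translation_invariance_property(seed, shift):
    rng = np.random.default_rng(seed)
    frame, top = random_frame_and_topology(rng, n_atoms=12)
    # force the selection neutral by zeroing total charge on a copy
    df = top.atoms.copy()
    df.loc[df.index[-1], "charge"] -= df["charge"].sum()  # selection net zero
    net = float(df.loc[df["group"] != "surface-OH", "charge"].sum())
    top2 = TopologyLite(atoms=df, net_charge=net)
    sel = np.arange(12)
    mu1 = compute_dipole(frame, top2, selection=sel)
    moved = MolecularFrame(index=0, box=frame.box,
                           coords=frame.coords + shift, com_distance=0.5)
    mu2 = compute_dipole(moved, top2, selection=sel)
    assert np.allclose(mu1, mu2, atol=1e-10)
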