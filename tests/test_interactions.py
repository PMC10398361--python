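"""Hydrogen bonds, ring-metal distances, contact occupancy, chain reversal,
water-in-slab counting — each checked against brute-force enumeration."""

import math

import numpy as np
import pytest

from bilayerlab.core import Selection, assign_leaflets
from bilayerlab.interactions import (
    ContactSeries,
    HBondCriteria,
    contact_occupancy,
    count_hydrogen_bonds,
    detect_chain_reversal,
    ring_metal_distance,
    waters_in_hydrophobic_slab,
)
from bilayerlab.synthetic import GeneratorParams, generate_bilayer_trajectory

from conftest import make_trajectory


def brute_force_hbonds(frame, donors, acceptors, criteria):
    """O(n^2) oracle: explicit loops, explicit minimum image."""
    box = np.asarray(frame.box)

    def mi(v):
        return v - box * np.round(v / box)

    n = 0
    for d, h in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            if np.linalg.norm(mi(frame.coordinates[a] - frame.coordinates[d])) > criteria.max_DA_distance:
                continue
            hd = mi(frame.coordinates[d] - frame.coordinates[h])
            ha = mi(frame.coordinates[a] - frame.coordinates[h])
            cosv = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
            angle = math.degrees(math.acos(np.clip(cosv, -1, 1)))
            if angle >= criteria.min_DHA_angle - 1e-9:
                n += 1
    return n


class TestHydrogenBonds:
    def _ohd_system(self, da_dist, angle_deg):
        """Donor O-H pointing at an acceptor O with given D-A distance and
        D-H...A angle."""
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([0.96, 0.0, 0.0])
        # place acceptor so that the angle at H between H->D and H->A is angle_deg
        ang = math.radians(180.0 - angle_deg)  # relative to the O-H direction
        a_dir = np.array([math.cos(ang), math.sin(ang), 0.0])
        # choose |H-A| so that |D-A| = da_dist
        # law of cosines in triangle D-H-A
        dh = 0.96
        cos_dha = math.cos(math.radians(angle_deg))
        # |DA|^2 = |DH|^2 + |HA|^2 - 2 |DH||HA| cos(DHA)
        coeffs = [1.0, -2 * dh * cos_dha, dh**2 - da_dist**2]
        ha = max(np.roots(coeffs).real)
        a = h + a_dir * ha
        specs = [("OD1", "O", 0), ("HD1", "H", 0), ("OA1", "O", 1)]
        traj = make_trajectory([[d, h, a]], (50.0, 50.0, 50.0), specs)
        return traj

    def test_ideal_linear_bond_counted(self):
        traj = self._ohd_system(2.8, 180.0)
        series = count_hydrogen_bonds(traj, [(0, 1)], Selection("a", (2,)))
        assert series.per_frame[0] == 1

    def test_beyond_distance_cutoff_not_counted(self):
        traj = self._ohd_system(3.4, 180.0)
        series = count_hydrogen_bonds(traj, [(0, 1)], Selection("a", (2,)))
        assert series.per_frame[0] == 0

    def test_below_angle_cutoff_not_counted(self):
        traj = self._ohd_system(2.8, 120.0)
        series = count_hydrogen_bonds(traj, [(0, 1)], Selection("a", (2,)))
        assert series.per_frame[0] == 0

    def test_non_hydrogen_donor_pair_rejected(self):
        traj = self._ohd_system(2.8, 180.0)
        with pytest.raises(Exception, match="not a hydrogen"):
            count_hydrogen_bonds(traj, [(0, 2)], Selection("a", (1,)))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n_donors, n_acceptors = 12, 26  # 50 atoms total
        box = (14.0, 14.0, 14.0)
        coords = []
        specs = []
        donors = []
        for i in range(n_donors):
            d = rng.uniform(0, 14, 3)
            h = d + rng.normal(size=3) * 0.4
            specs += [(f"OD{i}", "O", i), (f"HD{i}", "H", i)]
            donors.append((len(coords), len(coords) + 1))
            coords += [d, h]
        acc_start = len(coords)
        for i in range(n_acceptors):
            specs.append((f"OA{i}", "O", n_donors + i))
            coords.append(rng.uniform(0, 14, 3))
        traj = make_trajectory([coords], box, specs)
        acceptors = Selection("a", tuple(range(acc_start, acc_start + n_acceptors)))
        crit = HBondCriteria(max_DA_distance=3.5, min_DHA_angle=120.0)
        fast = count_hydrogen_bonds(traj, donors, acceptors, crit).per_frame[0]
        slow = brute_force_hbonds(traj.frames[0], donors, acceptors.indices, crit)
        assert fast == slow

    def test_invariant_under_full_box_translation(self):
        traj = self._ohd_system(2.8, 180.0)
        before = count_hydrogen_bonds(traj, [(0, 1)], Selection("a", (2,))).per_frame[0]
        moved = traj.frames[0].coordinates.copy()
        moved[2] += np.array([50.0, 0.0, 0.0])  # acceptor molecule shifted by Lx
        traj.frames[0].coordinates = moved
        after = count_hydrogen_bonds(traj, [(0, 1)], Selection("a", (2,))).per_frame[0]
        assert before == after == 1


def hexagon(center, radius=1.39, phase=0.0):
    return [
        center + radius * np.array([math.cos(phase + k * math.pi / 3),
                                    math.sin(phase + k * math.pi / 3), 0.0])
        for k in range(6)
    ]


class TestRingMetalDistance:
    def _ring_system(self, metal_pos, phase=0.0):
        coords = hexagon(np.zeros(3), phase=phase) + [np.asarray(metal_pos, dtype=float)]
        specs = [(f"CR{k}", "C", 0) for k in range(6)] + [("NI", "NI", 1)]
        return make_trajectory([coords], (60.0, 60.0, 60.0), specs)

    def test_centroid_distance(self):
        traj = self._ring_system([0.0, 0.0, 4.0])
        series = ring_metal_distance(traj, Selection("r", tuple(range(6))), Selection("m", (6,)))
        assert series.distances[0] == pytest.approx(4.0, abs=1e-12)

    def test_independent_of_ring_rotation(self):
        d0 = None
        for phase in (0.0, 0.4, 1.1):
            traj = self._ring_system([2.0, 1.0, 3.0], phase=phase)
            series = ring_metal_distance(traj, Selection("r", tuple(range(6))), Selection("m", (6,)))
            if d0 is None:
                d0 = series.distances[0]
            assert series.distances[0] == pytest.approx(d0, abs=1e-12)

    def test_wrong_sizes_rejected(self):
        traj = self._ring_system([0, 0, 4.0])
        with pytest.raises(Exception, match="6 atoms"):
            ring_metal_distance(traj, Selection("r", (0, 1)), Selection("m", (6,)))

    def test_crafted_population_fractions(self):
        distances = np.array([3.9] * 30 + [6.3] * 70)
        series = ContactSeries(label="x", distances=distances, bin_width=0.1)
        assert series.fraction_below(4.5) == pytest.approx(0.30)
        assert series.histogram_probability.sum() == pytest.approx(1.0)

    def test_fraction_below_monotone(self, rng):
        series = ContactSeries(label="x", distances=rng.uniform(2, 8, 500), bin_width=0.1)
        cuts = np.linspace(1, 9, 40)
        fracs = [series.fraction_below(c) for c in cuts]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))


class TestContactOccupancy:
    def _two_atom_traj(self, distances):
        specs = [("NI", "NI", 0), ("NE2", "N", 1)]
        frames = [[[0.0, 0.0, 0.0], [0.0, 0.0, float(d)]] for d in distances]
        return make_trajectory(frames, (50.0, 50.0, 50.0), specs)

    def test_always_bonded(self):
        traj = self._two_atom_traj([2.0, 2.1, 2.2])
        assert contact_occupancy(traj, Selection("a", (0,)), Selection("b", (1,)), 2.8) == 1.0

    def test_never_bonded(self):
        traj = self._two_atom_traj([5.0, 6.0])
        assert contact_occupancy(traj, Selection("a", (0,)), Selection("b", (1,)), 2.8) == 0.0

    def test_planted_94_percent(self):
        distances = [2.4] * 94 + [6.0] * 6
        traj = self._two_atom_traj(distances)
        assert contact_occupancy(
            traj, Selection("a", (0,)), Selection("b", (1,)), 2.8
        ) == pytest.approx(0.94)

    def test_generator_occupancy_recovered(self):
        from bilayerlab.synthetic import ContactParams

        p = GeneratorParams(
            n_lipids_per_leaflet=4, n_frames=50, chain_length=2, scd_targets=(0.2, 0.1),
            n_waters=0, contact=ContactParams(occupancy=0.94), seed=1,
        )
        traj, gt = generate_bilayer_trajectory(p)
        occ = contact_occupancy(
            traj, traj.selections["contact_a"], traj.selections["contact_b"], 2.8
        )
        assert occ == pytest.approx(gt["contact_occupancy"], abs=1e-12)


class TestChainReversal:
    def test_generator_fraction_recovered_exactly(self):
        p = GeneratorParams(
            n_lipids_per_leaflet=10, n_frames=20, chain_length=4,
            scd_targets=(0.2, 0.2, 0.1, 0.1), n_waters=0,
            oxpl_fraction=0.2, reversal_fraction=0.25, seed=6,
        )
        traj, gt = generate_bilayer_trajectory(p)
        leaf = assign_leaflets(traj.frames[0], traj.selections["phosphate"])
        result = detect_chain_reversal(
            traj, traj.selections["oxpl_terminal"], leaf, traj.selections["c2"]
        )
        assert result.fraction == pytest.approx(0.25, abs=1e-12)
        assert result.fraction == pytest.approx(gt["reversal_fraction"], abs=1e-12)
        assert result.flags.shape == (20, 4)

    def test_no_oxpl_warns_and_returns_empty(self):
        p = GeneratorParams(n_lipids_per_leaflet=4, n_frames=2, chain_length=2,
                            scd_targets=(0.2, 0.1), n_waters=0)
        traj, _ = generate_bilayer_trajectory(p)
        leaf = assign_leaflets(traj.frames[0], traj.selections["phosphate"])
        with pytest.warns(UserWarning, match="no oxPL"):
            result = detect_chain_reversal(
                traj, Selection("t", ()), leaf, traj.selections["c2"]
            )
        assert result.flags.size == 0
        assert math.isnan(result.fraction)


class TestWatersInSlab:
    def _system(self, water_zs):
        specs, coords = [], []
        mol = 0
        for z in (13.0, 13.0, -13.0, -13.0):
            specs.append(("P", "P", mol))
            coords.append([float(mol), 0.0, z + 5.0])
            mol += 1
        c2_start = len(coords)
        for lip, z in enumerate((13.0, 13.0, -13.0, -13.0)):
            # C2 belongs to the same lipid molecule as its phosphate
            specs.append(("C2", "C", lip))
            coords.append([float(lip), 1.0, z])
        w_start = len(coords)
        for z in water_zs:
            specs.append(("O", "O", mol))
            coords.append([1.0, 1.0, float(z)])
            mol += 1
        traj = make_trajectory([coords], (80.0, 80.0, 80.0), specs)
        p_sel = Selection("p", tuple(range(4)))
        c2 = Selection("c2", tuple(range(c2_start, c2_start + 4)))
        waters = Selection("w", tuple(range(w_start, len(coords))))
        leaf = assign_leaflets(traj.frames[0], p_sel)
        return traj, waters, c2, leaf

    def test_waters_outside_planes_not_counted(self):
        traj, w, c2, leaf = self._system([20.0, -20.0, 14.0])
        assert waters_in_hydrophobic_slab(traj, w, c2, leaf)[0] == 0

    def test_water_at_center_counted(self):
        traj, w, c2, leaf = self._system([0.0, 20.0])
        assert waters_in_hydrophobic_slab(traj, w, c2, leaf)[0] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        zs = rng.uniform(-30, 30, 40)
        traj, w, c2, leaf = self._system(zs)
        fast = waters_in_hydrophobic_slab(traj, w, c2, leaf)[0]
        slow = sum(1 for z in zs if -13.0 < z < 13.0)
        assert fast == slow
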