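"""Contact and population analyses: hydrogen bonds, aromatic-ring-to-metal
distances, coordination-site occupancy, oxidized-chain reversal, and water
counting in the hydrophobic slab.

Hydrogen bonds use the common geometric criterion — heavy-atom donor-acceptor
distance and D-H...A angle — with configurable thresholds (default 3.0 A and
135 deg; choices of this scale are standard for trajectory analysis).  Ring
centroids are unweighted means of the six ring-carbon positions.  All distance
computations respect the minimum-image convention of the per-frame box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from bilayerlab.core import (
    Frame,
    LeafletAssignment,
    Selection,
    Topology,
    Trajectory,
    TrajectoryError,
    histogram_edges,
    minimum_image,
)

__all__ = [
    "HBondCriteria",
    "ContactSeries",
    "ReversalResult",
    "count_hydrogen_bonds",
    "donor_pairs_from_selections",
    "ring_metal_distance",
    "contact_occupancy",
    "detect_chain_reversal",
    "waters_in_hydrophobic_slab",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion."""

    max_DA_distance: float = 3.0  # Angstrom, donor-acceptor heavy atoms
    min_DHA_angle: float = 135.0  # degrees at the hydrogen

    def __post_init__(self) -> None:
        if self.max_DA_distance <= 0:
            raise ValueError("max_DA_distance must be positive")
        if not 0 < self.min_DHA_angle <= 180:
            raise ValueError("min_DHA_angle must be in (0, 180]")


@dataclass
class ContactSeries:
    """Per-frame contact distances with histogram and cumulative populations."""

    label: str
    distances: np.ndarray  # Angstrom, one per frame
    bin_width: float
    histogram_bins: np.ndarray = field(init=False)  # bin centers
    histogram_probability: np.ndarray = field(init=False)  # sums to 1

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        edges = histogram_edges(float(d.min()), float(d.max()), self.bin_width)
        hist, _ = np.histogram(d, bins=edges)
        self.histogram_bins = (edges[:-1] + edges[1:]) / 2
        self.histogram_probability = hist / hist.sum()

    def fraction_below(self, cutoff: float) -> float:
        """Fraction of frames with distance <= cutoff (monotone in cutoff)."""
        return float(np.mean(self.distances <= cutoff))


@dataclass
class ReversalResult:
    """Chain-reversal flags: one row per frame, one column per oxPL lipid."""

    flags: np.ndarray  # (n_frames, n_oxpl) bool
    lipid_molecules: tuple[int, ...]

    @property
    def fraction(self) -> float:
        if self.flags.size == 0:
            return float("nan")
        return float(self.flags.mean())

    @property
    def per_lipid_fraction(self) -> np.ndarray:
        return self.flags.mean(axis=0)


def donor_pairs_from_selections(
    topology: Topology, donors: Selection, hydrogens: Selection
) -> list[tuple[int, int]]:
    """Pair each donor heavy atom with its hydrogens by bond distance proxy:
    a hydrogen belongs to the donor of the same molecule whose name shares the
    donor's numeric suffix, falling back to same-residue adjacency in the atom
    order."""
    pairs: list[tuple[int, int]] = []
    h_by_mol: dict[int, list[int]] = {}
    for h in hydrogens.indices:
        h_by_mol.setdefault(topology.atoms[h].molecule_id, []).append(h)
    for d in donors.indices:
        atom = topology.atoms[d]
        candidates = h_by_mol.get(atom.molecule_id, [])
        matched = [
            h
            for h in candidates
            if topology.atoms[h].residue_index == atom.residue_index
            and topology.atoms[h].name.startswith("H" + atom.name[1:])
        ]
        if not matched:
            matched = [h for h in candidates if abs(h - d) <= 2]
        if not matched:
            raise TrajectoryError(
                f"donor {atom.name} (molecule {atom.molecule_id}) has no hydrogen"
            )
        pairs.extend((d, h) for h in matched)
    return pairs


def count_hydrogen_bonds(
    traj: Trajectory,
    donors: Sequence[tuple[int, int]],
    acceptors: Selection,
    criteria: HBondCriteria = HBondCriteria(),
):
    """Per-frame hydrogen-bond counts between donor (D, H) pairs and acceptors.

    A bond is counted when the D-A distance is <= ``max_DA_distance`` and the
    D-H...A angle is >= ``min_DHA_angle``; the donor itself is excluded as its
    own acceptor.  Returns a BilayerMetricSeries (units: bonds per frame).
    """
    from bilayerlab.metrics import BilayerMetricSeries

    if len(donors) == 0 or len(acceptors) == 0:
        raise TrajectoryError("hydrogen-bond analysis requires donors and acceptors")
    top = traj.topology
    for d, h in donors:
        if top.atoms[h].element != "H":
            raise TrajectoryError(
                f"donor pair ({top.atoms[d].name}, {top.atoms[h].name}): second atom "
                "is not a hydrogen"
            )
    d_idx = np.array([d for d, _ in donors])
    h_idx = np.array([h for _, h in donors])
    a_idx = acceptors.index_array
    cos_min = np.cos(np.radians(criteria.min_DHA_angle))
    counts = np.zeros(traj.n_frames)
    for i, f in enumerate(traj.frames):
        box = f.box
        d_pos = f.coordinates[d_idx]
        h_pos = f.coordinates[h_idx]
        a_pos = f.coordinates[a_idx]
        da = minimum_image(a_pos[None, :, :] - d_pos[:, None, :], box)
        dist = np.linalg.norm(da, axis=2)
        close = dist <= criteria.max_DA_distance
        close &= a_idx[None, :] != d_idx[:, None]  # donor is not its own acceptor
        close &= a_idx[None, :] != h_idx[:, None]
        n = 0
        for j, k in zip(*np.nonzero(close)):
            hd = minimum_image(d_pos[j] - h_pos[j], box)
            ha = minimum_image(a_pos[k] - h_pos[j], box)
            cos_a = float(np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha)))
            # angle >= min  <=>  cos(angle) <= cos(min)
            if cos_a <= cos_min + 1e-12:
                n += 1
        counts[i] = n
    return BilayerMetricSeries.from_values(
        "hbond_count", counts, units="bonds", discard_fraction=0.0
    )


def ring_metal_distance(
    traj: Trajectory,
    ring: Selection,
    metal: Selection,
    bin_width: float = 0.1,
    cutoffs: Sequence[float] = (4.5,),
) -> ContactSeries:
    """Per-frame distance between the unweighted ring centroid and a metal ion.

    ``ring`` must contain exactly the 6 ring carbons and ``metal`` exactly one
    atom.  The returned series carries a 0.1 A histogram (probabilities sum to
    1) and can report the population fraction below any cutoff.
    """
    if len(ring) != 6:
        raise TrajectoryError(f"ring selection must have exactly 6 atoms, got {len(ring)}")
    if len(metal) != 1:
        raise TrajectoryError(f"metal selection must have exactly 1 atom, got {len(metal)}")
    r_idx = ring.index_array
    m_idx = metal.indices[0]
    distances = np.zeros(traj.n_frames)
    for i, f in enumerate(traj.frames):
        ring_pos = f.coordinates[r_idx]
        # image ring atoms to the copy nearest the first ring atom
        ring_pos = ring_pos[0] + minimum_image(ring_pos - ring_pos[0], f.box)
        centroid = ring_pos.mean(axis=0)
        disp = minimum_image(f.coordinates[m_idx] - centroid, f.box)
        distances[i] = np.linalg.norm(disp)
    series = ContactSeries(label=ring.label or "ring_metal", distances=distances, bin_width=bin_width)
    series.fractions = {float(c): series.fraction_below(c) for c in cutoffs}  # type: ignore[attr-defined]
    return series


def contact_occupancy(
    traj: Trajectory, a: Selection, b: Selection, cutoff: float
) -> float:
    """Fraction of frames where the minimum pairwise a-b distance is <= cutoff."""
    if len(a) == 0 or len(b) == 0:
        raise TrajectoryError("contact_occupancy: empty selection")
    a_idx, b_idx = a.index_array, b.index_array
    hits = 0
    for f in traj.frames:
        disp = minimum_image(
            f.coordinates[b_idx][None, :, :] - f.coordinates[a_idx][:, None, :], f.box
        )
        if float(np.linalg.norm(disp, axis=2).min()) <= cutoff:
            hits += 1
    return hits / traj.n_frames


def detect_chain_reversal(
    traj: Trajectory,
    terminal_carbons: Selection,
    leaflets: LeafletAssignment,
    c2_sel: Selection,
) -> ReversalResult:
    """Flag oxidized-chain reversal ("snorkeling") events.

    A (frame, lipid) pair is flagged when the shortened chain's terminal
    carbon sits farther from the bilayer midplane than its leaflet's mean
    |z| of C2 atoms — the aldehyde tip has crossed from the hydrophobic core
    past the ester region toward the headgroups.
    """
    if len(terminal_carbons) == 0:
        warnings.warn("no oxPL terminal carbons selected; empty reversal result", stacklevel=2)
        return ReversalResult(flags=np.zeros((traj.n_frames, 0), dtype=bool), lipid_molecules=())
    top = traj.topology
    upper_mols = set(leaflets.upper_molecules)
    term_idx = terminal_carbons.index_array
    term_mols = tuple(int(top.molecule_ids[i]) for i in term_idx)
    upper_c2 = np.array([i for i in c2_sel.indices if top.molecule_ids[i] in upper_mols])
    lower_c2 = np.array([i for i in c2_sel.indices if top.molecule_ids[i] not in upper_mols])
    if len(upper_c2) == 0 or len(lower_c2) == 0:
        raise TrajectoryError("chain reversal requires C2 atoms in both leaflets")
    flags = np.zeros((traj.n_frames, len(term_idx)), dtype=bool)
    for i, f in enumerate(traj.frames):
        z = f.coordinates[:, 2]
        thresholds = {
            True: float(np.abs(z[upper_c2]).mean()),
            False: float(np.abs(z[lower_c2]).mean()),
        }
        for j, (idx, mol) in enumerate(zip(term_idx, term_mols)):
            flags[i, j] = abs(z[idx]) > thresholds[mol in upper_mols]
    return ReversalResult(flags=flags, lipid_molecules=term_mols)


def waters_in_hydrophobic_slab(
    traj: Trajectory,
    water_O: Selection,
    c2_sel: Selection,
    leaflets: LeafletAssignment,
) -> np.ndarray:
    """Per-frame count of water oxygens strictly between the two C2 planes."""
    if len(water_O) == 0 or len(c2_sel) == 0:
        raise TrajectoryError("waters_in_hydrophobic_slab: empty selection")
    top = traj.topology
    upper_mols = set(leaflets.upper_molecules)
    upper_c2 = np.array([i for i in c2_sel.indices if top.molecule_ids[i] in upper_mols])
    lower_c2 = np.array([i for i in c2_sel.indices if top.molecule_ids[i] not in upper_mols])
    if len(upper_c2) == 0 or len(lower_c2) == 0:
        raise TrajectoryError("slab counting requires C2 atoms in both leaflets")
    w_idx = water_O.index_array
    counts = np.zeros(traj.n_frames, dtype=int)
    for i, f in enumerate(traj.frames):
        z = f.coordinates[:, 2]
        upper_plane = float(z[upper_c2].mean())
        lower_plane = float(z[lower_c2].mean())
        lo, hi = min(lower_plane, upper_plane), max(lower_plane, upper_plane)
        zw = z[w_idx]
        counts[i] = int(np.sum((zw > lo) & (zw < hi)))
    return counts
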