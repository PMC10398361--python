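"""Bilayer structural observables: area and volume per lipid, area
compressibility, thicknesses, electron density profiles, and deuterium order
parameters.

All quantities follow the standard membrane-simulation definitions:

* area per lipid           A_L = Lx * Ly / m_lipid          (per leaflet)
* volume per lipid         V_L = (V_box - n_w * V_w) / n_lipid
* area compressibility     K_A = k_B * T * <A> / var(A),  A = Lx * Ly
  (equivalently k_B * T * <A_L> / (m_lipid * var(A_L)))
* deuterium order param.   S_CD = <(3 cos^2 theta - 1) / 2>, theta the angle
  between each C-H bond and the bilayer normal (z); 1 = parallel to the
  normal, 0 = isotropic, -0.5 = in-plane.

Thicknesses h(P-P) and h(C2-C2) are distances between per-leaflet centers of
mass of the phosphate P and sn-2 C2 carbon selections.  Electron density
profiles decompose the z-resolved electron density into named atom groups
(phosphate, CH2, terminal CH3, peptide backbone, ...), normalized by the mean
in-plane box area and the bin width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from bilayerlab.core import (
    LeafletAssignment,
    Selection,
    Topology,
    Trajectory,
    TrajectoryError,
    center_of_mass,
    histogram_edges,
    minimum_image,
    phosphate_plane_shift,
)
from bilayerlab.reporting import block_average

__all__ = [
    "BilayerMetricSeries",
    "CompressibilityResult",
    "DensityProfile",
    "OrderParameterProfile",
    "area_per_lipid",
    "volume_per_lipid",
    "area_compressibility",
    "bilayer_thickness",
    "electron_density_profile",
    "order_parameters",
    "chain_triples_from_names",
    "BOLTZMANN_mN_per_m",
]

# k_B * T * <A>/var(A) with areas in Angstrom^2 gives J/Angstrom^2 = 1e23 mN/m,
# so in these units the prefactor is simply k_B in units of 1e-23 J/K.
BOLTZMANN_mN_per_m = 1.380649

TIP3P_WATER_VOLUME = 30.53  # Angstrom^3


@dataclass
class BilayerMetricSeries:
    """A per-frame scalar observable with its block-averaged summary."""

    name: str
    per_frame: np.ndarray
    units: str
    mean: float
    stderr: float
    n_frames_used: int
    n_discarded: int = 0

    @classmethod
    def from_values(
        cls,
        name: str,
        values: np.ndarray | Sequence[float],
        units: str = "",
        discard_fraction: float = 0.05,
        n_blocks: int = 5,
    ) -> "BilayerMetricSeries":
        """Summarize per-frame values, discarding an equilibration fraction
        from the front and block-averaging the rest for the standard error."""
        values = np.asarray(values, dtype=float)
        if not 0.0 <= discard_fraction < 1.0:
            raise ValueError("discard_fraction must be in [0, 1)")
        n_discard = int(discard_fraction * len(values))
        used = values[n_discard:]
        if len(used) == 0:
            raise ValueError("no frames left after equilibration discard")
        blocks = min(n_blocks, len(used))
        mean, stderr = block_average(used, n_blocks=blocks)
        return cls(
            name=name,
            per_frame=values,
            units=units,
            mean=mean,
            stderr=stderr,
            n_frames_used=len(used),
            n_discarded=n_discard,
        )

    @property
    def used_values(self) -> np.ndarray:
        return self.per_frame[self.n_discarded:]


@dataclass(frozen=True)
class CompressibilityResult:
    K_A: float  # mN/m
    A_L_mean: float  # Angstrom^2
    sigma2_AL: float  # Angstrom^4
    m_lipid: int
    T: float  # K


@dataclass
class DensityProfile:
    bin_centers: np.ndarray  # z, Angstrom
    densities: dict[str, np.ndarray]  # e-/Angstrom^3 per group
    bin_width: float
    mean_area: float  # Angstrom^2
    n_frames: int = 1

    def integral(self, group: str) -> float:
        """Integrated electron count of a group (equals its electron total for
        groups fully inside the z-range)."""
        return float(self.densities[group].sum() * self.bin_width * self.mean_area)


@dataclass
class OrderParameterProfile:
    chain_label: str
    carbon_index: np.ndarray  # position along the chain (1-based)
    scd: np.ndarray  # signed S_CD per carbon

    @property
    def abs_scd(self) -> np.ndarray:
        return np.abs(self.scd)

    def __post_init__(self) -> None:
        if np.any(self.scd < -0.5 - 1e-9) or np.any(self.scd > 1.0 + 1e-9):
            raise ValueError("S_CD outside the physical range [-0.5, 1]")


def _box_areas(traj: Trajectory) -> np.ndarray:
    return np.array([f.box[0] * f.box[1] for f in traj.frames])


def area_per_lipid(
    traj: Trajectory,
    m_lipid: int,
    discard_fraction: float = 0.05,
    n_blocks: int = 5,
) -> BilayerMetricSeries:
    """Per-frame area per lipid A_L = Lx * Ly / m_lipid (m_lipid per leaflet)."""
    if m_lipid <= 0:
        raise ValueError("m_lipid must be positive")
    values = _box_areas(traj) / m_lipid
    return BilayerMetricSeries.from_values(
        "A_L", values, units="Angstrom^2", discard_fraction=discard_fraction, n_blocks=n_blocks
    )


def volume_per_lipid(
    traj: Trajectory,
    n_w: int,
    n_lipid: int,
    v_w: float = TIP3P_WATER_VOLUME,
    discard_fraction: float = 0.05,
    n_blocks: int = 5,
) -> BilayerMetricSeries:
    """Per-frame volume per lipid V_L = (V_box - n_w * v_w) / n_lipid.

    ``n_lipid`` is the total lipid count (both leaflets).  A negative V_L
    (box smaller than the water volume) is reported with a warning.
    """
    if n_lipid <= 0:
        raise ValueError("n_lipid must be positive")
    if n_w < 0:
        raise ValueError("n_w must be non-negative")
    v_box = np.array([f.box[0] * f.box[1] * f.box[2] for f in traj.frames])
    values = (v_box - n_w * v_w) / n_lipid
    if np.any(values < 0):
        warnings.warn("negative V_L: box volume smaller than total water volume", stacklevel=2)
    return BilayerMetricSeries.from_values(
        "V_L", values, units="Angstrom^3", discard_fraction=discard_fraction, n_blocks=n_blocks
    )


def area_compressibility(
    areas: BilayerMetricSeries, T: float, m_lipid: int
) -> CompressibilityResult:
    """Isothermal area compressibility modulus from equilibrium area fluctuations.

    K_A = k_B * T * <A_L> / (m_lipid * var(A_L)), reported in mN/m; the
    variance is the unbiased sample variance over post-equilibration frames.
    Equivalent to the whole-box form k_B * T * <A> / var(A) with A = Lx * Ly.
    """
    values = areas.used_values
    if len(values) < 2:
        raise ValueError("K_A needs at least 2 frames")
    var = float(values.var(ddof=1))
    if var == 0.0:
        raise ValueError("rigid box; K_A undefined")
    mean_al = float(values.mean())
    k_a = BOLTZMANN_mN_per_m * T * mean_al / (m_lipid * var)
    return CompressibilityResult(K_A=k_a, A_L_mean=mean_al, sigma2_AL=var, m_lipid=m_lipid, T=T)


def _intersect(sel: Selection, leaflet: Selection, label: str) -> Selection:
    members = set(leaflet.indices)
    idx = tuple(i for i in sel.indices if i in members)
    return Selection(label, idx)


def bilayer_thickness(
    traj: Trajectory,
    sel: Selection,
    leaflets: LeafletAssignment,
    discard_fraction: float = 0.05,
    n_blocks: int = 5,
) -> BilayerMetricSeries:
    """Per-frame |COM_z(upper) - COM_z(lower)| of a P or C2 selection.

    With the phosphate selection this is the headgroup-to-headgroup thickness
    h(P-P); with the sn-2 C2 selection the hydrophobic thickness h(C2-C2).
    """
    upper = _intersect(sel, leaflets.upper, sel.label + "_upper")
    lower = _intersect(sel, leaflets.lower, sel.label + "_lower")
    if len(upper) == 0 or len(lower) == 0:
        raise TrajectoryError("thickness: a leaflet has no selected atoms")
    values = np.array(
        [
            abs(float(center_of_mass(f, upper)[2]) - float(center_of_mass(f, lower)[2]))
            for f in traj.frames
        ]
    )
    return BilayerMetricSeries.from_values(
        f"h({sel.label or 'sel'})", values, units="Angstrom",
        discard_fraction=discard_fraction, n_blocks=n_blocks,
    )


def electron_density_profile(
    traj: Trajectory,
    groups: Mapping[str, Selection],
    bin_width: float = 0.5,
    center_sel: Selection | None = None,
    include_total: bool = True,
    symmetrize: bool = False,
) -> DensityProfile:
    """Frame-averaged electron density along z, decomposed into atom groups.

    Each frame contributes a histogram of atom electron counts along z
    (recentred so the mean z of ``center_sel`` — normally the phosphate P
    atoms — is zero); the average is divided by the bin volume
    (mean Lx * Ly * bin_width).  Empty groups are omitted with a warning.
    Leaflet symmetrization is off by default.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    kept: dict[str, Selection] = {}
    for label, sel in groups.items():
        if len(sel) == 0:
            warnings.warn(f"density group {label!r} is empty; omitted", stacklevel=2)
        else:
            kept[label] = sel

    shifts = [
        phosphate_plane_shift(f, center_sel) if center_sel is not None else 0.0
        for f in traj.frames
    ]
    z_min, z_max = np.inf, -np.inf
    for f, s in zip(traj.frames, shifts):
        z = f.coordinates[:, 2] - s
        z_min = min(z_min, z.min())
        z_max = max(z_max, z.max())
    edges = histogram_edges(float(z_min), float(z_max), bin_width)
    centers = (edges[:-1] + edges[1:]) / 2

    mean_area = float(_box_areas(traj).mean())
    electrons = traj.topology.electrons
    densities: dict[str, np.ndarray] = {}
    targets = dict(kept)
    if include_total:
        targets["total"] = Selection("total", tuple(range(traj.topology.n_atoms)))
    for label, sel in targets.items():
        idx = sel.index_array
        acc = np.zeros(len(centers))
        for f, s in zip(traj.frames, shifts):
            z = f.coordinates[idx, 2] - s
            hist, _ = np.histogram(z, bins=edges, weights=electrons[idx])
            acc += hist
        dens = acc / (traj.n_frames * mean_area * bin_width)
        if symmetrize:
            dens = (dens + dens[::-1]) / 2
        densities[label] = dens

    return DensityProfile(
        bin_centers=centers,
        densities=densities,
        bin_width=bin_width,
        mean_area=mean_area,
        n_frames=traj.n_frames,
    )


ChainTriples = Sequence[Sequence[tuple[int, tuple[int, ...]]]]


def order_parameters(
    traj: Trajectory, chains: Mapping[str, ChainTriples]
) -> dict[str, OrderParameterProfile]:
    """Deuterium order parameters per chain carbon.

    ``chains`` maps a chain label (sn-1, sn-2, oxPL, ...) to a list over carbon
    positions; each position is a list of (carbon_index, hydrogen_indices)
    pairs, one per lipid.  S_CD for a position is the average of
    (3 cos^2 theta - 1)/2 over all its C-H bonds, lipids and frames, with
    theta the angle between the (minimum-image) C-H vector and z.  The signed
    value is retained; take ``abs_scd`` for the conventional |S_CD| plots.
    """
    profiles: dict[str, OrderParameterProfile] = {}
    for chain_label, per_carbon in chains.items():
        scd = np.zeros(len(per_carbon))
        for k, entries in enumerate(per_carbon):
            total, count = 0.0, 0
            for c_idx, h_idxs in entries:
                if len(h_idxs) == 0:
                    raise TrajectoryError(
                        f"chain {chain_label!r}, carbon position {k + 1}: no attached "
                        "hydrogens listed; explicit-H topologies are required"
                    )
                for f in traj.frames:
                    vec = minimum_image(
                        f.coordinates[list(h_idxs)] - f.coordinates[c_idx], f.box
                    )
                    norms = np.linalg.norm(vec, axis=1)
                    cos_t = vec[:, 2] / norms
                    total += float(((3.0 * cos_t**2 - 1.0) / 2.0).sum())
                    count += len(h_idxs)
            scd[k] = total / count
        profiles[chain_label] = OrderParameterProfile(
            chain_label=chain_label,
            carbon_index=np.arange(1, len(per_carbon) + 1),
            scd=scd,
        )
    return profiles


def chain_triples_from_names(
    topology: Topology, residue_pattern: str, carbon_names: Sequence[str]
) -> ChainTriples:
    """Build per-carbon (C, hydrogens) index lists from an H-naming convention.

    For a carbon named ``C7`` the attached hydrogens are the atoms of the same
    molecule named ``H7...`` (``H71``, ``H72``, ...).  Returns one entry per
    carbon position, each a list of (carbon_index, hydrogen_indices) over all
    matching lipids.
    """
    import fnmatch as _fn

    by_mol: dict[int, dict[str, int]] = {}
    for i, a in enumerate(topology.atoms):
        if _fn.fnmatchcase(a.residue_name, residue_pattern):
            by_mol.setdefault(a.molecule_id, {})[a.name] = i
    result: list[list[tuple[int, tuple[int, ...]]]] = []
    for cname in carbon_names:
        suffix = cname[1:]
        entries = []
        for mol, names in sorted(by_mol.items()):
            if cname not in names:
                continue
            prefix = "H" + suffix
            # one trailing character distinguishes H31/H32 (of C3) from H131 (of C13)
            h_idxs = tuple(
                idx
                for n, idx in sorted(names.items())
                if n.startswith(prefix) and len(n) == len(prefix) + 1
            )
            entries.append((names[cname], h_idxs))
        result.append(entries)
    return result
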