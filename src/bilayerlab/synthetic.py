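"""Synthetic bilayer + peptide trajectory generator with planted ground truth.

The generator emulates only the statistical structure the analyses read, at
desk scale: two leaflets of coarse toy lipids (one phosphate P, one sn-2 C2
carbon, an acyl chain of carbons each carrying two explicit hydrogens) on a
jittered grid, box areas drawn from a prescribed mean/variance, leaflet P and
C2 planes at the target thicknesses, per-carbon C-H polar angles chosen so the
planted order parameters are exact, an optional ideal alpha-helix embedded at
a prescribed tilt/rotation/depth, optional shortened oxidized chains with
deterministic reversal events, an optional metal-coordination/ring-contact
site, and waters outside the phosphate planes.

Every planted observable is recorded in a :class:`GroundTruth` mapping and is
recoverable by the corresponding analysis operation — exactly on noise-free
settings, statistically under sampling noise.  Identical seeds give identical
trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from bilayerlab.core import Atom, Frame, Selection, Topology, Trajectory
from bilayerlab.helix import build_reference_helix
from bilayerlab.metrics import BOLTZMANN_mN_per_m, TIP3P_WATER_VOLUME

__all__ = [
    "GeneratorParams",
    "PeptideParams",
    "ContactParams",
    "GroundTruth",
    "generate_bilayer_trajectory",
    "default_selection_config",
    "default_chain_map",
    "write_ground_truth",
    "read_ground_truth",
    "PRESETS",
]

_GOLDEN_ANGLE = 137.50776405003785  # degrees; fills azimuths evenly without RNG


@dataclass(frozen=True)
class PeptideParams:
    """Planted helix orientation and depth.

    ``z_true`` is the signed depth of the full backbone center of mass below
    the upper-leaflet phosphate plane (negative = toward the bilayer center).
    """

    n_residues: int = 22
    tau_true: float = 95.0  # degrees
    rho_true: float = 261.0  # degrees
    z_true: float = -7.8  # Angstrom
    segment_N: tuple[int, int] = (5, 10)
    segment_C: tuple[int, int] = (14, 20)
    jitter_sigma: float = 0.0  # Angstrom of per-frame Gaussian backbone noise

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_true < 180.0:
            raise ValueError("tau_true must be in (0, 180) degrees")
        if not 0.0 <= self.rho_true < 360.0:
            raise ValueError("rho_true must be in [0, 360) degrees")
        for first, last in (self.segment_N, self.segment_C):
            if not 1 <= first <= last <= self.n_residues:
                raise ValueError("segment outside peptide")


@dataclass(frozen=True)
class ContactParams:
    """Planted metal-coordination and ring-contact geometry.

    In the occupied fraction of frames the His-like nitrogen sits at
    ``his_close`` from the metal and the ring centroid at ``ring_close``;
    otherwise at the far distances.
    """

    occupancy: float = 0.94
    his_close: float = 2.4  # Angstrom, coordination-bond scale
    his_far: float = 6.0
    ring_close: float = 3.9
    ring_far: float = 6.3
    ring_radius: float = 1.39  # phenyl C6 ring

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


def _default_scd_targets(chain_length: int) -> tuple[float, ...]:
    # plateau near the headgroups decaying along the chain, |S| ~ 0.2 -> 0.1
    return tuple(round(0.21 - 0.11 * k / max(chain_length - 1, 1), 4) for k in range(chain_length))


@dataclass(frozen=True)
class GeneratorParams:
    """Study-scale defaults: 40 lipids/leaflet (P/L = 1:40), T = 313 K,
    ~56 waters per lipid, free-bilayer area per lipid 67.1 A^2, thicknesses
    h(P-P) = 37.5 A and h(C2-C2) = 27.4 A, volume per lipid 1206 A^3, and an
    area variance chosen so the planted K_A is 254 mN/m."""

    n_lipids_per_leaflet: int = 40
    n_frames: int = 200
    seed: int = 0
    area_mean: float | None = None  # total box area; default 67.1 A^2 per lipid
    area_variance: float | None = None  # default: variance giving K_A = 254 mN/m
    temperature: float = 313.0  # K
    h_PP_target: float = 37.5  # Angstrom
    h_C2C2_target: float = 27.4  # Angstrom
    scd_targets: tuple[float, ...] | None = None  # defaults to a decaying profile
    chain_length: int = 10  # carbons per acyl chain (toy scale)
    n_waters: int | None = None  # default 56 waters per lipid
    v_water: float = TIP3P_WATER_VOLUME
    v_lipid: float = 1206.0  # Angstrom^3, sets the box height
    oxpl_fraction: float = 0.0  # fraction of lipids with a shortened reversed-capable chain
    reversal_fraction: float = 0.0  # fraction of oxPL frames with chain reversal
    scd_mode: str = "fixed"  # "fixed" (exact per frame) or "stochastic"
    area_autocorrelation: float = 0.0  # AR(1) coefficient for block-averaging tests
    peptide: PeptideParams | None = None
    contact: ContactParams | None = None

    def __post_init__(self) -> None:
        if self.area_variance is not None and self.area_variance < 0:
            raise ValueError("area_variance must be non-negative")
        if self.h_C2C2_target >= self.h_PP_target:
            raise ValueError("infeasible geometry: h_C2C2 must be smaller than h_PP")
        for frac in (self.oxpl_fraction, self.reversal_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.scd_mode not in ("fixed", "stochastic"):
            raise ValueError("scd_mode must be 'fixed' or 'stochastic'")
        if self.scd_targets is not None:
            if len(self.scd_targets) != self.chain_length:
                raise ValueError("scd_targets must have one value per chain carbon")
            for s in self.scd_targets:
                if not -0.5 <= s <= 1.0:
                    raise ValueError("each scd_target must be in [-0.5, 1]")
        if not 0.0 <= self.area_autocorrelation < 1.0:
            raise ValueError("area_autocorrelation must be in [0, 1)")

    @property
    def resolved_scd_targets(self) -> tuple[float, ...]:
        if self.scd_targets is not None:
            return tuple(self.scd_targets)
        return _default_scd_targets(self.chain_length)

    @property
    def resolved_area_mean(self) -> float:
        if self.area_mean is not None:
            return self.area_mean
        return 67.1 * self.n_lipids_per_leaflet  # free-bilayer A_L scale

    @property
    def resolved_area_variance(self) -> float:
        if self.area_variance is not None:
            return self.area_variance
        # variance implied by the free-bilayer compressibility K_A = 254 mN/m
        return BOLTZMANN_mN_per_m * self.temperature * self.resolved_area_mean / 254.0

    @property
    def resolved_n_waters(self) -> int:
        if self.n_waters is not None:
            return self.n_waters
        return 56 * self.n_lipids_total

    @property
    def n_lipids_total(self) -> int:
        return 2 * self.n_lipids_per_leaflet

    @property
    def ox_chain_length(self) -> int:
        return max(2, self.chain_length // 2)


@dataclass
class GroundTruth:
    """Planted observable values, keyed by the names the analyses report."""

    values: dict[str, float]
    scd: np.ndarray  # per-carbon planted S_CD (standard chains)
    scd_ox: np.ndarray  # per-carbon planted S_CD (oxidized chains; empty if none)
    params: GeneratorParams

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def _polar_angle_for_scd(s: float) -> float:
    """theta with (3 cos^2 theta - 1)/2 = s, measured from the bilayer normal."""
    return math.acos(math.sqrt((2.0 * s + 1.0) / 3.0))


def _rotation_for_tau_rho(tau_deg: float, rho_deg: float) -> np.ndarray:
    """Rotation whose tilt/azimuth decomposition is exactly (tau, rho):
    R = Rot_y(tau - 90 deg) @ Rot_x(rho)."""
    a = math.radians(tau_deg - 90.0)
    g = math.radians(rho_deg)
    rot_y = np.array(
        [[math.cos(a), 0.0, math.sin(a)], [0.0, 1.0, 0.0], [-math.sin(a), 0.0, math.cos(a)]]
    )
    rot_x = np.array(
        [[1.0, 0.0, 0.0], [0.0, math.cos(g), -math.sin(g)], [0.0, math.sin(g), math.cos(g)]]
    )
    return rot_y @ rot_x


def _deterministic_subset(rng: np.random.Generator, n_total: int, fraction: float) -> np.ndarray:
    """Boolean mask with exactly round(fraction * n_total) True entries,
    positions shuffled by the seeded generator."""
    k = int(round(fraction * n_total))
    mask = np.zeros(n_total, dtype=bool)
    mask[rng.permutation(n_total)[:k]] = True
    return mask


def generate_bilayer_trajectory(
    params: GeneratorParams | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Generate a toy bilayer(+peptide) trajectory and its ground truth.

    See the module docstring for the construction.  The returned trajectory
    carries pre-resolved selections (phosphate, c2, water_O, pep_backbone,
    oxpl_terminal, metal, his_n, ring, ch2, ch3) matching
    :func:`default_selection_config`.
    """
    if params is None:
        params = GeneratorParams()
    rng = np.random.default_rng(params.seed)
    n_leaf = params.n_lipids_per_leaflet
    n_frames = params.n_frames
    scd = np.array(params.resolved_scd_targets)
    chain_len = params.chain_length
    ox_len = params.ox_chain_length

    # --- per-frame box areas -------------------------------------------------
    area_mean = params.resolved_area_mean
    area_variance = params.resolved_area_variance
    n_waters = params.resolved_n_waters
    sigma = math.sqrt(area_variance)
    if area_variance == 0.0:
        areas = np.full(n_frames, area_mean)
    elif params.area_autocorrelation > 0.0:
        phi = params.area_autocorrelation
        eps_sd = sigma * math.sqrt(1.0 - phi * phi)
        areas = np.empty(n_frames)
        areas[0] = area_mean + rng.normal(0.0, sigma)
        for t in range(1, n_frames):
            areas[t] = area_mean + phi * (areas[t - 1] - area_mean) + rng.normal(0.0, eps_sd)
    else:
        areas = rng.normal(area_mean, sigma, size=n_frames)
    areas = np.clip(areas, 0.25 * area_mean, None)
    # box height keeps the planted volume per lipid exact on every frame
    heights = (params.n_lipids_total * params.v_lipid + n_waters * params.v_water) / areas

    # --- which lipids are oxidized ------------------------------------------
    n_ox_per_leaf = int(round(params.oxpl_fraction * n_leaf))
    is_ox = [i < n_ox_per_leaf for i in range(n_leaf)]  # same pattern in both leaflets

    # --- lipid grid ----------------------------------------------------------
    side = math.sqrt(area_mean)
    nx = math.ceil(math.sqrt(n_leaf))
    spacing = side / nx
    lipid_xy = np.zeros((2, n_leaf, 2))  # leaflet, lipid, xy (reference positions)
    for leaf in range(2):
        k = 0
        for iy in range(nx):
            for ix in range(nx):
                if k >= n_leaf:
                    break
                jitter = rng.uniform(-0.15 * spacing, 0.15 * spacing, size=2)
                lipid_xy[leaf, k] = (
                    (ix + 0.5) * spacing - side / 2 + jitter[0],
                    (iy + 0.5) * spacing - side / 2 + jitter[1],
                )
                k += 1

    half_pp = params.h_PP_target / 2.0
    half_c2 = params.h_C2C2_target / 2.0
    dz_by_len = {
        chain_len: (half_c2 - 2.0) / (chain_len + 1),
        ox_len: (half_c2 - 2.0) / (chain_len + 1),  # same spacing; ox chain just shorter
    }
    ch_bond = 1.09

    # --- topology ------------------------------------------------------------
    atoms: list[Atom] = []
    # bookkeeping for coordinate assembly
    lipid_atom_slices: list[tuple[int, int]] = []  # start, stop per lipid
    lipid_leaflet: list[int] = []
    lipid_is_ox: list[bool] = []
    mol = 0
    res = 0

    def add_atom(name: str, element: str, res_name: str, res_idx: int, mol_id: int) -> None:
        from bilayerlab.core import ELEMENTS

        mass, z_num = ELEMENTS[element]
        atoms.append(
            Atom(
                name=name, element=element, mass=mass, electrons=z_num,
                residue_name=res_name, residue_index=res_idx, molecule_id=mol_id,
            )
        )

    for leaf in range(2):
        for i in range(n_leaf):
            ox = is_ox[i]
            res += 1
            start = len(atoms)
            res_name = "OXL" if ox else "LIP"
            add_atom("P", "P", res_name, res, mol)
            add_atom("C2", "C", res_name, res, mol)
            length = ox_len if ox else chain_len
            for k in range(1, length + 1):
                cn = k + 2
                add_atom(f"C{cn}", "C", res_name, res, mol)
                add_atom(f"H{cn}1", "H", res_name, res, mol)
                add_atom(f"H{cn}2", "H", res_name, res, mol)
            if ox:
                add_atom("OD", "O", res_name, res, mol)  # aldehyde oxygen
            lipid_atom_slices.append((start, len(atoms)))
            lipid_leaflet.append(leaf)
            lipid_is_ox.append(ox)
            mol += 1

    water_start = len(atoms)
    for w in range(n_waters):
        res += 1
        add_atom("O", "O", "HOH", res, mol)
        mol += 1

    pep_start = len(atoms)
    reference = None
    pep_base = None
    if params.peptide is not None:
        pp = params.peptide
        reference = build_reference_helix(pp.n_residues)
        rot = _rotation_for_tau_rho(pp.tau_true, pp.rho_true)
        placed = reference.coordinates @ rot.T
        from bilayerlab.core import ELEMENTS

        bb_masses = np.array(
            [ELEMENTS["N"][0], ELEMENTS["C"][0], ELEMENTS["C"][0]] * pp.n_residues
        )
        com_z = float(np.average(placed[:, 2], weights=bb_masses))
        placed[:, 2] += (half_pp + pp.z_true) - com_z
        pep_base = placed
        pep_mol = mol
        for r in range(pp.n_residues):
            for name, elem in (("N", "N"), ("CA", "C"), ("C", "C")):
                add_atom(name, elem, "ALA", r + 1, pep_mol)
        mol += 1

    contact_start = len(atoms)
    if params.contact is not None:
        res += 1
        add_atom("NI", "NI", "NID", res, mol)
        mol += 1
        res += 1
        add_atom("NE2", "N", "HIS", res, mol)
        mol += 1
        res += 1
        for k in range(6):
            add_atom(f"CR{k + 1}", "C", "RNG", res, mol)
        mol += 1

    topology = Topology(atoms)
    n_atoms = len(atoms)

    # --- static geometry pieces ----------------------------------------------
    base = np.zeros((n_atoms, 3))

    # azimuth schedule for fixed mode: golden-angle sequence, frame-constant
    def fixed_azimuth(lipid_index: int, carbon: int, h: int) -> float:
        j = (lipid_index * (chain_len + 1) + carbon) * 2 + h
        return math.radians((j * _GOLDEN_ANGLE) % 360.0)

    thetas = np.array([_polar_angle_for_scd(s) for s in scd])

    # waters: uniform in the slabs outside the P planes, fixed across frames
    lz_nominal = float(heights.mean())
    slab_lo = half_pp + 1.5
    slab_hi = max(lz_nominal / 2.0 - 2.0, slab_lo + 1.0)
    n_up = n_waters - n_waters // 2
    water_xy = rng.uniform(-side / 2, side / 2, size=(n_waters, 2))
    water_z = np.empty(n_waters)
    water_z[:n_up] = rng.uniform(slab_lo, slab_hi, size=n_up)
    water_z[n_up:] = -rng.uniform(slab_lo, slab_hi, size=n_waters - n_up)
    base[water_start : water_start + n_waters, :2] = water_xy
    base[water_start : water_start + n_waters, 2] = water_z

    # reversal schedule: deterministic count over (frame, ox-lipid) pairs
    ox_lipids = [j for j, o in enumerate(lipid_is_ox) if o]
    n_ox_total = len(ox_lipids)
    if n_ox_total > 0 and params.reversal_fraction > 0:
        rev_mask = _deterministic_subset(
            rng, n_frames * n_ox_total, params.reversal_fraction
        ).reshape(n_frames, n_ox_total)
    else:
        rev_mask = np.zeros((n_frames, n_ox_total), dtype=bool)
    realized_reversal = float(rev_mask.mean()) if n_ox_total else float("nan")

    # contact schedule
    if params.contact is not None:
        occ_mask = _deterministic_subset(rng, n_frames, params.contact.occupancy)
        realized_occupancy = float(occ_mask.mean())
    else:
        occ_mask = None
        realized_occupancy = float("nan")

    # stochastic-mode orientation draws are made per frame below, after the
    # schedules, so the rng consumption order is fixed and seed-reproducible

    def chain_orientation(theta: float, phi: float) -> np.ndarray:
        return np.array(
            [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta)]
        )

    frames: list[Frame] = []
    for t in range(n_frames):
        coords = base.copy()
        scale = math.sqrt(areas[t] / area_mean)
        box = (
            math.sqrt(areas[t]),
            math.sqrt(areas[t]),
            float(heights[t]),
        )
        for j, (start, stop) in enumerate(lipid_atom_slices):
            leaf = lipid_leaflet[j]
            sgn = 1.0 if leaf == 0 else -1.0
            cx, cy = lipid_xy[leaf, j - leaf * n_leaf]
            cx, cy = cx * scale, cy * scale
            ox = lipid_is_ox[j]
            length = ox_len if ox else chain_len
            dz = dz_by_len[length]
            a = start
            coords[a] = (cx, cy, sgn * half_pp)  # P
            coords[a + 1] = (cx, cy, sgn * half_c2)  # C2
            reversed_now = False
            if ox and j in ox_lipids:
                reversed_now = bool(rev_mask[t, ox_lipids.index(j)])
            for k in range(1, length + 1):
                idx = a + 2 + (k - 1) * 3
                if reversed_now and k == length:
                    cz = sgn * (half_c2 + 3.0)  # aldehyde tip past the ester region
                else:
                    cz = sgn * (half_c2 - k * dz)
                coords[idx] = (cx, cy, cz)
                s_k = scd[min(k - 1, len(scd) - 1)]
                theta = thetas[min(k - 1, len(thetas) - 1)]
                for h in range(2):
                    if params.scd_mode == "fixed":
                        phi = fixed_azimuth(j, k, h)
                        direction = chain_orientation(theta, phi)
                    else:
                        direction = _stochastic_ch_direction(rng, s_k)
                    coords[idx + 1 + h] = coords[idx] + ch_bond * direction
            if ox:
                od_idx = stop - 1
                tip = coords[a + 2 + (length - 1) * 3]
                coords[od_idx] = tip + np.array([0.0, 0.0, sgn * 1.22])  # C=O
        if pep_base is not None:
            pp = params.peptide
            pep_coords = pep_base
            if pp.jitter_sigma > 0:
                pep_coords = pep_base + rng.normal(0.0, pp.jitter_sigma, size=pep_base.shape)
            coords[pep_start : pep_start + len(pep_base)] = pep_coords
        if params.contact is not None:
            cp = params.contact
            occupied = bool(occ_mask[t])
            metal_pos = np.array([side / 4, side / 4, half_pp - 2.0])
            his_d = cp.his_close if occupied else cp.his_far
            ring_d = cp.ring_close if occupied else cp.ring_far
            coords[contact_start] = metal_pos
            coords[contact_start + 1] = metal_pos + np.array([0.0, 0.0, his_d])
            centroid = metal_pos + np.array([ring_d, 0.0, 0.0])
            for k in range(6):
                ang = math.radians(60.0 * k)
                coords[contact_start + 2 + k] = centroid + cp.ring_radius * np.array(
                    [0.0, math.cos(ang), math.sin(ang)]
                )
        frames.append(Frame(coords, box, topology))

    traj = Trajectory(topology, frames, frame_spacing=None)
    for label, patterns in default_selection_config(params).items():
        traj.selections[label] = topology.select([tuple(p) for p in patterns], label=label)

    # --- ground truth --------------------------------------------------------
    values: dict[str, float] = {
        "A_L": area_mean / n_leaf,
        "V_L": params.v_lipid,
        "h_PP": params.h_PP_target,
        "h_C2C2": params.h_C2C2_target,
        "reversal_fraction": realized_reversal,
        "contact_occupancy": realized_occupancy,
    }
    if area_variance > 0:
        values["K_A"] = (
            BOLTZMANN_mN_per_m * params.temperature * area_mean / area_variance
        )
    if params.peptide is not None:
        pp = params.peptide
        values["tau_N"] = values["tau_C"] = values["tau_full"] = pp.tau_true
        values["rho_N"] = values["rho_C"] = values["rho_full"] = pp.rho_true
        bb_z = pep_base[:, 2]
        seg_masses = bb_masses.reshape(pp.n_residues, 3)
        bb_z_res = bb_z.reshape(pp.n_residues, 3)

        def seg_depth(first: int, last: int) -> float:
            zs = bb_z_res[first - 1 : last].ravel()
            ms = seg_masses[first - 1 : last].ravel()
            return float(np.average(zs, weights=ms) - half_pp)

        values["z_N"] = seg_depth(*pp.segment_N)
        values["z_C"] = seg_depth(*pp.segment_C)
        values["z_pep"] = seg_depth(1, pp.n_residues)
    gt = GroundTruth(
        values=values,
        scd=scd.copy(),
        scd_ox=scd[:ox_len].copy() if n_ox_total else np.array([]),
        params=params,
    )
    return traj, gt


def _stochastic_ch_direction(rng: np.random.Generator, s: float) -> np.ndarray:
    """Random C-H direction whose expected (3 cos^2 theta - 1)/2 equals s.

    Mixture construction: with probability p the bond takes the pure
    orientation (along z for s >= 0, in-plane for s < 0), otherwise it is
    isotropic; p = s for s >= 0 and p = -2 s for s < 0.
    """
    if s >= 0:
        p, pure_in_plane = s, False
    else:
        p, pure_in_plane = -2.0 * s, True
    if rng.random() < p:
        phi = rng.uniform(0.0, 2.0 * math.pi)
        if pure_in_plane:
            return np.array([math.cos(phi), math.sin(phi), 0.0])
        return np.array([0.0, 0.0, 1.0 if rng.random() < 0.5 else -1.0])
    # isotropic on the sphere
    z = rng.uniform(-1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    r = math.sqrt(max(1.0 - z * z, 0.0))
    return np.array([r * math.cos(phi), r * math.sin(phi), z])


def default_selection_config(params: GeneratorParams) -> dict[str, list[tuple[str, str]]]:
    """Selection definitions matching the generator's atom naming."""
    chain_len = params.chain_length
    ox_len = params.ox_chain_length
    terminal = f"C{chain_len + 2}"
    ox_terminal = f"C{ox_len + 2}"
    ch2_patterns: list[tuple[str, str]] = []
    for res in ("LIP", "OXL"):
        last = chain_len + 2 if res == "LIP" else ox_len + 2
        for cn in range(3, last):  # all chain carbons except the terminal one
            ch2_patterns += [(res, f"C{cn}"), (res, f"H{cn}?")]
        ch2_patterns.append((res, "C2"))
    ch3_patterns = [("LIP", terminal), ("LIP", f"H{chain_len + 2}?"),
                    ("OXL", ox_terminal), ("OXL", f"H{ox_len + 2}?")]
    cfg = {
        "phosphate": [("LIP", "P"), ("OXL", "P")],
        "c2": [("LIP", "C2"), ("OXL", "C2")],
        "water_O": [("HOH", "O")],
        "pep_backbone": [("ALA", "N"), ("ALA", "CA"), ("ALA", "C")],
        "oxpl_terminal": [("OXL", ox_terminal)],
        "metal": [("NID", "NI")],
        "his_n": [("HIS", "NE2")],
        "ring": [("RNG", "CR?")],
        "contact_a": [("NID", "NI")],
        "contact_b": [("HIS", "NE2")],
        "ch2": ch2_patterns,
        "ch3": ch3_patterns,
    }
    return cfg


def default_chain_map(params: GeneratorParams) -> dict[str, dict[str, object]]:
    """Chain definitions (for order parameters) matching the generator naming."""
    chains: dict[str, dict[str, object]] = {
        "sn": {
            "residue": "LIP",
            "carbons": [f"C{k}" for k in range(3, params.chain_length + 3)],
        }
    }
    if params.oxpl_fraction > 0:
        chains["oxPL"] = {
            "residue": "OXL",
            "carbons": [f"C{k}" for k in range(3, params.ox_chain_length + 3)],
        }
    return chains


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write ground truth as machine-readable key = value text."""
    lines = [f"{k} = {v!r}" for k, v in sorted(gt.values.items())]
    lines += [f"S_CD_{i + 1} = {float(s)!r}" for i, s in enumerate(gt.scd)]
    lines += [f"S_CD_ox_{i + 1} = {float(s)!r}" for i, s in enumerate(gt.scd_ox)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            out[k.strip()] = float(v)
    return out


def _preset_popc_popg(n_frames: int, seed: int) -> GeneratorParams:
    return GeneratorParams(n_frames=n_frames, seed=seed, peptide=PeptideParams(),
                           contact=ContactParams())


def _preset_oxpl(n_frames: int, seed: int) -> GeneratorParams:
    return GeneratorParams(
        n_frames=n_frames, seed=seed,
        oxpl_fraction=0.1, reversal_fraction=0.1,
        h_PP_target=36.4, h_C2C2_target=26.3, v_lipid=1183.0,
        peptide=PeptideParams(), contact=ContactParams(),
    )


PRESETS = {
    "popc-popg": _preset_popc_popg,
    "oxpl": _preset_oxpl,
}
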