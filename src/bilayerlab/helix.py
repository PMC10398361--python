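"""Helix orientation analysis: reference-helix construction, Kabsch superposition,
and decomposition of the fitted rotation into tilt and azimuthal rotation.

Conventions
-----------
The ideal reference helix (phi = -61 deg, psi = -45 deg) is built from internal
coordinates and rigidly re-oriented so that its long axis lies along +x (in the
membrane plane) and the radial vector of the central residue's C-alpha points
along +z.  With z the bilayer normal, the zero-rotation baseline therefore
corresponds to a tilt of tau = 90 deg (helix lying flat in the membrane) and an
azimuthal rotation of rho = 0.

For an observed backbone segment, the optimal proper rotation R from reference
to observation is found by Kabsch superposition.  The helix axis is h = R x;
tau = arccos(h . z).  rho is the signed angle, right-handed about h, from the
component of the lab z axis perpendicular to h to the rotated reference radial
vector R z, mapped to [0, 360).  Absolute rho values depend on this anchor
choice; differences in rho are convention-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from bilayerlab.core import (
    Frame,
    Selection,
    Topology,
    Trajectory,
    TrajectoryError,
    center_of_mass,
    unwrap_molecules,
)

__all__ = [
    "ReferenceHelix",
    "OrientationSeries",
    "build_reference_helix",
    "kabsch",
    "fit_segment_orientation",
    "orientation_series",
    "insertion_depth",
    "backbone_rmsd",
    "segment_selection",
    "rotation_euler_zyz",
    "measure_dihedral",
]

# Ideal backbone internal coordinates (Engh-Huber-like standard values)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_C_N_CA = 121.7
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_PHI = -61.0
_PSI = -45.0
_OMEGA = 180.0


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """NeRF placement: position D with |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = torsion (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = _normalize(c - b)
    n = _normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor), -bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _normalize(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


@dataclass(frozen=True)
class ReferenceHelix:
    """Ideal poly-alanine-like alpha-helix backbone (N, CA, C per residue).

    ``coordinates`` is a (3*n_residues, 3) array in the canonical orientation:
    axis along +x, central-residue radial vector along +z, centroid at the
    origin.
    """

    coordinates: np.ndarray
    n_residues: int

    @property
    def axis(self) -> np.ndarray:
        return np.array([1.0, 0.0, 0.0])

    def atom_rows(self, first_res: int, last_res: int) -> np.ndarray:
        """Row indices of backbone atoms for residues first..last (1-based, inclusive)."""
        if not (1 <= first_res <= last_res <= self.n_residues):
            raise ValueError(
                f"segment {first_res}..{last_res} outside helix of {self.n_residues} residues"
            )
        return np.arange((first_res - 1) * 3, last_res * 3)

    def segment_coordinates(self, first_res: int, last_res: int) -> np.ndarray:
        return self.coordinates[self.atom_rows(first_res, last_res)]

    @property
    def ca_coordinates(self) -> np.ndarray:
        return self.coordinates[1::3]


def build_reference_helix(n_residues: int) -> ReferenceHelix:
    """Construct the ideal reference helix with phi/psi = -61/-45 degrees.

    The backbone is generated residue-by-residue from standard bond lengths and
    angles; the result is re-oriented so the first principal axis of the
    C-alpha positions lies along +x (pointing N-terminus to C-terminus) and the
    radial offset of the central residue's C-alpha points along +z.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues for a well-defined helix axis")
    coords = np.zeros((3 * n_residues, 3))
    # first residue placed in the xy-plane
    coords[0] = (0.0, 0.0, 0.0)  # N1
    coords[1] = (_BOND_N_CA, 0.0, 0.0)  # CA1
    ang = math.radians(_ANGLE_N_CA_C)
    coords[2] = coords[1] + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])  # C1
    for i in range(1, n_residues):
        n_prev, ca_prev, c_prev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        n_new = _place_atom(n_prev, ca_prev, c_prev, _BOND_C_N, _ANGLE_CA_C_N, _PSI)
        ca_new = _place_atom(ca_prev, c_prev, n_new, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        c_new = _place_atom(c_prev, n_new, ca_new, _BOND_CA_C, _ANGLE_N_CA_C, _PHI)
        coords[3 * i] = n_new
        coords[3 * i + 1] = ca_new
        coords[3 * i + 2] = c_new

    # canonical orientation
    ca = coords[1::3]
    centroid = ca.mean(axis=0)
    coords -= coords.mean(axis=0)
    ca = coords[1::3]
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    # rotate axis -> +x
    r1 = _rotation_between(axis, np.array([1.0, 0.0, 0.0]))
    coords = coords @ r1.T
    ca = coords[1::3]
    centroid = ca.mean(axis=0)
    mid = n_residues // 2
    radial = ca[mid] - centroid
    radial[0] = 0.0  # perpendicular component
    if np.linalg.norm(radial) < 1e-9:
        raise ValueError("degenerate radial vector for central residue")
    gamma = math.atan2(radial[1], radial[2])
    cg, sg = math.cos(gamma), math.sin(gamma)
    rot_x = np.array([[1.0, 0.0, 0.0], [0.0, cg, -sg], [0.0, sg, cg]])
    coords = coords @ rot_x.T
    coords -= coords.mean(axis=0)
    return ReferenceHelix(coordinates=coords, n_residues=n_residues)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b (Rodrigues)."""
    a = _normalize(np.asarray(a, dtype=float))
    b = _normalize(np.asarray(b, dtype=float))
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180-degree flip about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = _normalize(np.cross(a, perp))
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper rotation R minimizing ||R p_i - q_i|| over centered point sets.

    Returns (R, rmsd).  The reflection branch of the SVD solution is rejected so
    R is always a proper rotation (det R = +1).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("point sets must have matching shapes")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    diff = pc @ r.T - qc
    rmsd = float(np.sqrt((diff**2).sum() / len(p)))
    return r, rmsd


@dataclass
class OrientationSeries:
    """Per-frame helix orientation for one named segment."""

    segment_label: str
    tau: np.ndarray  # degrees, [0, 180]
    rho: np.ndarray  # degrees, [0, 360); NaN where undefined (tau ~ 0 or 180)
    z: np.ndarray  # insertion depth, Angstrom (signed)
    fit_rmsd: np.ndarray  # Angstrom

    @property
    def mean_tau(self) -> float:
        return float(np.mean(self.tau))

    @property
    def mean_rho(self) -> float:
        """Circular mean of rho mapped to [0, 360)."""
        rho = self.rho[~np.isnan(self.rho)]
        if rho.size == 0:
            return float("nan")
        rad = np.radians(rho)
        return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)

    @property
    def mean_z(self) -> float:
        return float(np.mean(self.z))


# below this the azimuth reference (z projected off the axis) is at the
# numerical noise floor of arccos near +-1, so rho is reported as undefined
_TAU_DEGENERACY_TOL = 1e-5  # degrees


def fit_segment_orientation(
    frame: Frame,
    segment: Selection,
    reference: ReferenceHelix,
    residues: tuple[int, int] | None = None,
) -> tuple[float, float, float]:
    """Tilt tau, azimuthal rotation rho, and fit RMSD for one backbone segment.

    ``segment`` must list the observed backbone N/CA/C atoms in residue order;
    ``residues`` picks the matching reference residues (defaults to the full
    reference).  Returns (tau_deg, rho_deg, fit_rmsd); rho is NaN when tau is
    within 1e-5 deg of 0 or 180 (azimuth reference vanishes).
    """
    if residues is None:
        ref_coords = reference.coordinates
    else:
        ref_coords = reference.segment_coordinates(*residues)
    obs = unwrap_molecules(frame, segment.index_array)
    if obs.shape != ref_coords.shape:
        raise TrajectoryError(
            f"segment has {len(obs)} atoms but reference segment has {len(ref_coords)}"
        )
    spread = np.linalg.norm(obs - obs.mean(axis=0), axis=1)
    if np.max(spread) < 1e-9:
        raise TrajectoryError("degenerate segment: all atoms coincident")
    r, rmsd = kabsch(ref_coords, obs)
    h = r @ np.array([1.0, 0.0, 0.0])
    cos_tau = float(np.clip(h[2], -1.0, 1.0))
    tau = math.degrees(math.acos(cos_tau))
    if tau < _TAU_DEGENERACY_TOL or tau > 180.0 - _TAU_DEGENERACY_TOL:
        return tau, float("nan"), rmsd
    z_lab = np.array([0.0, 0.0, 1.0])
    e = z_lab - cos_tau * h
    e = e / np.linalg.norm(e)
    radial = r @ z_lab  # rotated reference radial vector, perpendicular to h
    sin_comp = float(np.dot(h, np.cross(e, radial)))
    cos_comp = float(np.dot(e, radial))
    rho = math.degrees(math.atan2(sin_comp, cos_comp)) % 360.0
    return tau, rho, rmsd


def rotation_euler_zyz(r: np.ndarray) -> tuple[float, float, float]:
    """z-y-z intrinsic Euler angles (degrees) of a rotation matrix, for interoperability."""
    from scipy.spatial.transform import Rotation

    return tuple(Rotation.from_matrix(r).as_euler("ZYZ", degrees=True))


def segment_selection(
    topology: Topology,
    first_res: int,
    last_res: int,
    residue_names: Sequence[str] = ("ALA",),
    backbone_names: Sequence[str] = ("N", "CA", "C"),
    label: str = "",
) -> Selection:
    """Backbone selection for a residue range, ordered residue-by-residue N, CA, C."""
    name_order = {n: k for k, n in enumerate(backbone_names)}
    picked = [
        (a.residue_index, name_order[a.name], i)
        for i, a in enumerate(topology.atoms)
        if a.residue_name in residue_names
        and a.name in name_order
        and first_res <= a.residue_index <= last_res
    ]
    picked.sort()
    return Selection(label or f"backbone_{first_res}_{last_res}", tuple(i for *_, i in picked))


def insertion_depth(frame: Frame, backbone: Selection, leaflet_P: Selection) -> float:
    """Signed depth of the backbone center of mass below its leaflet's P plane.

    The peptide is assigned to the nearest phosphate plane; positions toward
    the bilayer center are negative for either leaflet.
    """
    if len(backbone) == 0 or len(leaflet_P) == 0:
        raise TrajectoryError("insertion_depth: empty selection")
    z_p = frame.coordinates[leaflet_P.index_array, 2]
    mid = z_p.mean()
    upper = z_p[z_p > mid]
    lower = z_p[z_p <= mid]
    com_z = float(center_of_mass(frame, backbone)[2])
    if upper.size == 0 or lower.size == 0 or np.ptp(z_p) == 0.0:
        # single plane of P atoms: treat it as the (upper) reference plane
        return com_z - float(z_p.mean())
    up_mean, lo_mean = float(upper.mean()), float(lower.mean())
    if abs(com_z - up_mean) <= abs(com_z - lo_mean):
        return com_z - up_mean
    return lo_mean - com_z


def orientation_series(
    traj: Trajectory,
    reference: ReferenceHelix,
    segments: Mapping[str, tuple[int, int]],
    leaflet_P: Selection,
    residue_names: Sequence[str] = ("ALA",),
    backbone_names: Sequence[str] = ("N", "CA", "C"),
    stride: int = 1,
) -> dict[str, OrientationSeries]:
    """Per-frame (tau, rho, z, RMSD) for each named residue segment.

    ``segments`` maps labels (e.g. ``"N"``, ``"C"``, ``"full"``) to 1-based
    inclusive residue ranges of the reference helix.
    """
    results: dict[str, OrientationSeries] = {}
    frames = traj.frames[::stride]
    for label, (first, last) in segments.items():
        sel = segment_selection(
            traj.topology, first, last, residue_names=residue_names, backbone_names=backbone_names
        )
        taus, rhos, zs, rmsds = [], [], [], []
        for frame in frames:
            tau, rho, rmsd = fit_segment_orientation(frame, sel, reference, residues=(first, last))
            taus.append(tau)
            rhos.append(rho)
            rmsds.append(rmsd)
            zs.append(insertion_depth(frame, sel, leaflet_P))
        results[label] = OrientationSeries(
            segment_label=label,
            tau=np.array(taus),
            rho=np.array(rhos),
            z=np.array(zs),
            fit_rmsd=np.array(rmsds),
        )
    return results


def backbone_rmsd(traj: Trajectory, sel: Selection, mode: str = "to_mean"):
    """Per-frame best-fit RMSD of the selected atoms to a reference structure.

    ``mode="to_mean"`` (default) superposes onto the iteratively refined average
    structure; ``mode="to_first"`` onto frame 1.  Rigid-body motion is removed
    by Kabsch superposition before the deviation is measured.
    """
    from bilayerlab.metrics import BilayerMetricSeries

    if mode not in ("to_mean", "to_first"):
        raise ValueError(f"unknown mode {mode!r}")
    idx = sel.index_array
    if len(idx) == 0:
        raise TrajectoryError("backbone_rmsd: empty selection")
    coords = [unwrap_molecules(f, idx) for f in traj.frames]
    if mode == "to_mean" and len(coords) < 2:
        raise TrajectoryError("to_mean mode requires at least 2 frames")
    if mode == "to_first":
        ref = coords[0]
    else:
        ref = coords[0]
        for _ in range(5):  # converges in a couple of passes for rigid-ish segments
            aligned = []
            ref_c = ref - ref.mean(axis=0)
            for c in coords:
                r, _ = kabsch(c, ref_c)
                cc = c - c.mean(axis=0)
                aligned.append(cc @ r.T)
            new_ref = np.mean(aligned, axis=0)
            if np.max(np.abs(new_ref - ref_c)) < 1e-10:
                ref = new_ref
                break
            ref = new_ref
    ref_c = ref - ref.mean(axis=0)
    values = []
    for c in coords:
        _, rmsd = kabsch(c - c.mean(axis=0), ref_c)
        values.append(rmsd)
    return BilayerMetricSeries.from_values(
        "backbone_rmsd_" + mode, np.array(values), units="Angstrom", discard_fraction=0.0
    )
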