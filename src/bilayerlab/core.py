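"""Trajectory/topology data model, multi-model PDB I/O, and shared geometry utilities.

The in-memory model is deliberately small: a :class:`Topology` (atom identities,
masses, electron counts, residue/molecule grouping), a :class:`Frame` (one set of
coordinates plus the periodic box), and a :class:`Trajectory` tying them together.
Trajectories are exchanged as multi-model PDB files (MODEL/ENDMDL blocks, one
CRYST1 per model for the fluctuating box).  Only orthorhombic boxes are
supported; CRYST1 records with angles other than 90 degrees are rejected.

Atom selections are plain index sets resolved from (residue-name pattern,
atom-name pattern) pairs — no selection mini-language.
"""

from __future__ import annotations

import fnmatch
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "LeafletAssignment",
    "read_trajectory",
    "write_trajectory",
    "select",
    "center_of_mass",
    "assign_leaflets",
    "phosphate_plane_shift",
    "minimum_image",
]

# Standard atomic masses (Da) and atomic numbers, keyed on element symbol.
# PDB files carry neither; electrons default to the neutral-atom count.
ELEMENTS: dict[str, tuple[float, int]] = {
    "H": (1.008, 1),
    "C": (12.011, 6),
    "N": (14.007, 7),
    "O": (15.999, 8),
    "F": (18.998, 9),
    "NA": (22.990, 11),
    "MG": (24.305, 12),
    "P": (30.974, 15),
    "S": (32.06, 16),
    "CL": (35.45, 17),
    "K": (39.098, 19),
    "CA": (40.078, 20),
    "MN": (54.938, 25),
    "FE": (55.845, 26),
    "NI": (58.693, 28),
    "CU": (63.546, 29),
    "ZN": (65.38, 30),
}


class TrajectoryError(ValueError):
    """Raised for malformed trajectory files or invalid selections."""


@dataclass(frozen=True)
class Atom:
    """One atom of the topology.

    ``electrons`` defaults to the atomic number of ``element`` (neutral atom);
    partial charges are ignored throughout.
    """

    name: str
    element: str
    mass: float
    electrons: int
    residue_name: str
    residue_index: int
    molecule_id: int

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")
        if self.electrons < 1:
            raise ValueError(f"atom {self.name}: electron count must be >= 1")


class Topology:
    """Ordered atom list with cached per-atom arrays."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        seen: set[tuple[int, int, str]] = set()
        for a in self.atoms:
            key = (a.molecule_id, a.residue_index, a.name)
            if key in seen:
                raise TrajectoryError(
                    f"duplicate atom {a.name} in molecule {a.molecule_id}, "
                    f"residue {a.residue_index}"
                )
            seen.add(key)
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.electrons = np.array([a.electrons for a in self.atoms], dtype=float)
        self.molecule_ids = np.array([a.molecule_id for a in self.atoms], dtype=int)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def select(
        self, patterns: Sequence[tuple[str, str]] | tuple[str, str], label: str = ""
    ) -> "Selection":
        """Resolve (residue-name pattern, atom-name pattern) pairs to a Selection.

        Patterns are shell-style globs matched case-sensitively against
        ``residue_name`` and ``name``.
        """
        if isinstance(patterns, tuple) and len(patterns) == 2 and isinstance(patterns[0], str):
            patterns = [patterns]  # type: ignore[list-item]
        indices = [
            i
            for i, a in enumerate(self.atoms)
            if any(
                fnmatch.fnmatchcase(a.residue_name, rp) and fnmatch.fnmatchcase(a.name, ap)
                for rp, ap in patterns
            )
        ]
        return Selection(label=label, indices=tuple(indices))


@dataclass(frozen=True)
class Selection:
    """A labelled, ordered set of atom indices into a topology."""

    label: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise TrajectoryError(f"selection {self.label!r}: duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def index_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


@dataclass
class Frame:
    """Coordinates (Angstrom) for every topology atom plus the periodic box."""

    coordinates: np.ndarray  # (n_atoms, 3)
    box: tuple[float, float, float]  # Lx, Ly, Lz, Angstrom
    topology: Topology | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError("coordinates must be an (n, 3) array")
        if any(L <= 0 for L in self.box):
            raise TrajectoryError("box lengths must be positive")
        if self.topology is not None and len(self.topology) != len(self.coordinates):
            raise TrajectoryError(
                f"coordinate count {len(self.coordinates)} does not match "
                f"topology atom count {len(self.topology)}"
            )


@dataclass
class Trajectory:
    """An ordered sequence of frames over one topology."""

    topology: Topology
    frames: list[Frame]
    frame_spacing: float | None = None  # ns between stored frames, metadata only
    selections: dict[str, Selection] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory must contain at least one frame")
        for f in self.frames:
            if f.topology is None:
                f.topology = self.topology
            if len(f.coordinates) != len(self.topology):
                raise TrajectoryError("frame atom count does not match topology")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def select(self, patterns, label: str = "") -> Selection:
        return self.topology.select(patterns, label)


@dataclass(frozen=True)
class LeafletAssignment:
    """Partition of lipid molecules into upper and lower leaflets."""

    upper: Selection  # all atoms of upper-leaflet lipid molecules
    lower: Selection
    upper_molecules: tuple[int, ...]
    lower_molecules: tuple[int, ...]

    @property
    def m_lipid_upper(self) -> int:
        return len(self.upper_molecules)

    @property
    def m_lipid_lower(self) -> int:
        return len(self.lower_molecules)


# ---------------------------------------------------------------------------
# periodic-box helpers


def histogram_edges(vmin: float, vmax: float, bin_width: float) -> np.ndarray:
    """Bin edges on a bin_width-aligned grid guaranteed to cover [vmin, vmax].

    The outermost edges are nudged outward so floating-point drift in the
    aligned grid can never exclude the extreme data values.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = math.floor(vmin / bin_width) * bin_width
    n = max(int(math.ceil((vmax - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n + 1)
    while edges[-1] < vmax:
        edges = np.append(edges, edges[-1] + bin_width)
    edges[0] = min(edges[0], vmin)
    edges[-1] = max(edges[-1], vmax) + 1e-9 * bin_width
    return edges


def minimum_image(disp: np.ndarray, box: Sequence[float]) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    disp = np.asarray(disp, dtype=float)
    b = np.asarray(box, dtype=float)
    return disp - b * np.round(disp / b)


def unwrap_molecules(frame: Frame, indices: np.ndarray) -> np.ndarray:
    """Return coordinates with each molecule made whole across periodic boundaries.

    Within a molecule, each atom is imaged to the periodic copy nearest the
    preceding atom (sequential unwrapping, anchored at the molecule's first
    atom).  Successive atoms of a molecule are close in space, so this also
    handles molecules whose extent exceeds half the box — where imaging
    everything to the first atom would wrap the far end.  Prevents
    center-of-mass artifacts for molecules split across boundaries.
    """
    if frame.topology is None:
        return frame.coordinates[indices]
    coords = frame.coordinates[indices].copy()
    mol_ids = frame.topology.molecule_ids[indices]
    box = np.asarray(frame.box, dtype=float)
    for mol in np.unique(mol_ids):
        mask = mol_ids == mol
        sub = coords[mask]
        if len(sub) > 1:
            steps = minimum_image(np.diff(sub, axis=0), box)
            sub = sub[0] + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        coords[mask] = sub
    return coords


def center_of_mass(
    frame: Frame, sel: Selection, weighting: str = "mass"
) -> np.ndarray:
    """Weighted mean position of the selected atoms, after molecule-wise unwrapping.

    Parameters
    ----------
    weighting:
        ``"mass"`` for the mass-weighted center of mass, ``"geometric"`` for the
        unweighted centroid.
    """
    if len(sel) == 0:
        raise TrajectoryError(f"selection {sel.label!r} is empty")
    if weighting not in ("mass", "geometric"):
        raise ValueError(f"unknown weighting {weighting!r}")
    idx = sel.index_array
    coords = unwrap_molecules(frame, idx)
    if weighting == "mass":
        if frame.topology is None:
            raise TrajectoryError("mass weighting requires a topology")
        w = frame.topology.masses[idx]
    else:
        w = np.ones(len(idx))
    return np.asarray(np.average(coords, axis=0, weights=w))


def assign_leaflets(frame: Frame, phosphate_sel: Selection) -> LeafletAssignment:
    """Assign each lipid to a leaflet by its phosphate P position.

    A lipid goes to the upper leaflet iff its P atom's z exceeds the mean z of
    all selected P atoms.  ``phosphate_sel`` must contain exactly one P per
    lipid molecule.
    """
    if frame.topology is None:
        raise TrajectoryError("leaflet assignment requires a topology")
    if len(phosphate_sel) == 0:
        raise TrajectoryError("phosphate selection is empty")
    idx = phosphate_sel.index_array
    z = frame.coordinates[idx, 2]
    if np.ptp(z) == 0.0:
        raise TrajectoryError("degenerate bilayer: all phosphate atoms at identical z")
    mols = frame.topology.molecule_ids[idx]
    if len(np.unique(mols)) != len(mols):
        raise TrajectoryError("phosphate selection must contain one P atom per lipid")
    mean_z = z.mean()
    upper_mols = tuple(int(m) for m in mols[z > mean_z])
    lower_mols = tuple(int(m) for m in mols[z <= mean_z])
    all_ids = frame.topology.molecule_ids
    upper_idx = tuple(int(i) for i in np.flatnonzero(np.isin(all_ids, upper_mols)))
    lower_idx = tuple(int(i) for i in np.flatnonzero(np.isin(all_ids, lower_mols)))
    return LeafletAssignment(
        upper=Selection("upper_leaflet", upper_idx),
        lower=Selection("lower_leaflet", lower_idx),
        upper_molecules=upper_mols,
        lower_molecules=lower_mols,
    )


def phosphate_plane_shift(frame: Frame, phosphate_sel: Selection) -> float:
    """z-offset that recenters the frame so the mean phosphate z is zero.

    All z-resolved analyses subtract this shift; the bilayer midplane is then
    z = 0 by construction.
    """
    idx = phosphate_sel.index_array
    return float(frame.coordinates[idx, 2].mean())


# ---------------------------------------------------------------------------
# multi-model PDB I/O (fixed-column, PDB 3.3)


def _parse_cryst1(line: str) -> tuple[float, float, float]:
    a = float(line[6:15])
    b = float(line[15:24])
    c = float(line[24:33])
    alpha = float(line[33:40])
    beta = float(line[40:47])
    gamma = float(line[47:54])
    if not (abs(alpha - 90) < 1e-6 and abs(beta - 90) < 1e-6 and abs(gamma - 90) < 1e-6):
        raise TrajectoryError(
            f"non-orthorhombic box (angles {alpha}, {beta}, {gamma}); only 90 degree "
            "angles are supported"
        )
    return (a, b, c)


def _element_from_fields(line: str, name: str) -> str:
    elem = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not elem:
        # fall back on the leading letters of the atom name
        stripped = name.strip().lstrip("0123456789")
        if len(stripped) >= 2 and stripped[:2].upper() in ELEMENTS:
            elem = stripped[:2].upper()
        else:
            elem = stripped[:1].upper()
    if elem not in ELEMENTS:
        raise TrajectoryError(f"unknown element symbol {elem!r} for atom {name.strip()!r}")
    return elem


def read_trajectory(
    path: str | Path,
    selection_config: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    frame_spacing: float | None = None,
) -> Trajectory:
    """Read a multi-model PDB file into a Trajectory.

    One Frame per MODEL block (a file without MODEL records is a single frame).
    The box is taken from the CRYST1 record inside each model, falling back to
    the first CRYST1 seen if later models omit it.  Molecules are delimited by
    TER records; without TER, every residue is its own molecule.  Electron
    counts are the neutral-atom atomic numbers of the element symbols.

    ``selection_config`` maps labels to lists of (residue-name pattern,
    atom-name pattern) pairs; resolved selections are attached to the returned
    trajectory.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    first_box: tuple[float, float, float] | None = None
    models: list[dict] = []
    current: dict | None = None
    saw_model_record = False

    def new_model() -> dict:
        return {"coords": [], "atoms": [], "box": None}

    for line in lines:
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model_record = True
            current = new_model()
            models.append(current)
        elif rec.startswith("CRYST1"):
            box = _parse_cryst1(line)
            if first_box is None:
                first_box = box
            if current is not None:
                current["box"] = box
        elif rec in ("ATOM  ", "HETATM"):
            if current is None:
                current = new_model()
                models.append(current)
            name = line[12:16]
            res_name = line[17:21].strip()
            res_seq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            current["coords"].append((x, y, z))
            current["atoms"].append((name.strip(), res_name, res_seq, _element_from_fields(line, name)))
        elif rec.startswith("TER"):
            if current is not None:
                current["atoms"].append(("TER", "", -1, ""))
        elif rec.startswith("ENDMDL"):
            current = None

    models = [m for m in models if m["coords"]]
    if not models:
        raise TrajectoryError(f"{path}: no atoms found")
    if first_box is None:
        raise TrajectoryError(f"{path}: no box information (no CRYST1 record in any model)")

    # topology from the first model
    atoms: list[Atom] = []
    mol_id = 0
    prev_res: tuple[str, int] | None = None
    saw_ter_in_first = any(a[0] == "TER" for a in models[0]["atoms"])
    for name, res_name, res_seq, elem in models[0]["atoms"]:
        if name == "TER":
            mol_id += 1
            prev_res = None
            continue
        if not saw_ter_in_first:
            if prev_res is not None and (res_name, res_seq) != prev_res:
                mol_id += 1
            prev_res = (res_name, res_seq)
        mass, z_num = ELEMENTS[elem]
        atoms.append(
            Atom(
                name=name,
                element=elem,
                mass=mass,
                electrons=z_num,
                residue_name=res_name,
                residue_index=res_seq,
                molecule_id=mol_id,
            )
        )
    topology = Topology(atoms)

    frames: list[Frame] = []
    n_expected = len(topology)
    for i, m in enumerate(models):
        n = len(m["coords"])
        if n != n_expected:
            raise TrajectoryError(
                f"{path}: model {i + 1} has {n} atoms but model 1 has {n_expected}"
            )
        box = m["box"] if m["box"] is not None else first_box
        frames.append(Frame(np.array(m["coords"], dtype=float), box, topology))

    traj = Trajectory(topology, frames, frame_spacing=frame_spacing)
    if saw_model_record and len(models) >= 1:
        pass  # model count is implied by len(frames)
    if selection_config:
        for label, patterns in selection_config.items():
            traj.selections[label] = topology.select(
                [tuple(p) for p in patterns], label=label
            )
    return traj


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB with per-model CRYST1 records.

    Coordinates are written to the PDB's 3-decimal field precision; TER records
    delimit molecules so molecule grouping round-trips.
    """
    path = Path(path)
    top = traj.topology
    out: list[str] = []
    for i_frame, frame in enumerate(traj.frames, start=1):
        out.append(f"MODEL     {i_frame:4d}")
        a, b, c = frame.box
        out.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
        prev_mol: int | None = None
        serial = 0
        for i, atom in enumerate(top.atoms):
            if prev_mol is not None and atom.molecule_id != prev_mol:
                out.append("TER")
            prev_mol = atom.molecule_id
            serial = (serial % 99999) + 1
            x, y, z = frame.coordinates[i]
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            res_seq = atom.residue_index % 10000
            out.append(
                f"ATOM  {serial:5d} {name:4.4s} {atom.residue_name:<4.4s}{res_seq:5d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element:>2.2s}"
            )
        out.append("TER")
        out.append("ENDMDL")
    out.append("END")
    path.write_text("\n".join(out) + "\n")
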