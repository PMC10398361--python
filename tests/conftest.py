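import numpy as np
import pytest

from bilayerlab.core import Atom, Frame, Selection, Topology, Trajectory

ELEMENT_DEFAULTS = {
    "H": (1.008, 1),
    "C": (12.011, 6),
    "N": (14.007, 7),
    "O": (15.999, 8),
    "P": (30.974, 15),
    "NI": (58.693, 28),
}


def make_atoms(specs):
    """specs: list of (name, element) or (name, element, molecule_id)."""
    atoms = []
    for i, spec in enumerate(specs):
        name, element = spec[0], spec[1]
        mol = spec[2] if len(spec) > 2 else i
        mass, z = ELEMENT_DEFAULTS[element]
        atoms.append(
            Atom(
                name=name, element=element, mass=mass, electrons=z,
                residue_name="RES", residue_index=mol + 1, molecule_id=mol,
            )
        )
    return atoms


def make_trajectory(coords_per_frame, boxes, specs=None):
    """Build a Trajectory from raw coordinates.

    coords_per_frame: list of (n, 3) arrays; boxes: one (Lx, Ly, Lz) per frame
    or a single box; specs: atom specs for make_atoms (default: one carbon per
    atom, each its own molecule).
    """
    coords_per_frame = [np.asarray(c, dtype=float) for c in coords_per_frame]
    n = len(coords_per_frame[0])
    if specs is None:
        specs = [(f"C{i + 1}", "C") for i in range(n)]
    topology = Topology(make_atoms(specs))
    if isinstance(boxes, tuple):
        boxes = [boxes] * len(coords_per_frame)
    frames = [Frame(c, b, topology) for c, b in zip(coords_per_frame, boxes)]
    return Trajectory(topology, frames)


def all_atoms(traj, label="all"):
    return Selection(label, tuple(range(traj.topology.n_atoms)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
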