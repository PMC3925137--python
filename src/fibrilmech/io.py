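"""Reading and writing structures/trajectories (multi-MODEL PDB, multi-frame XYZ).

PDB files are handled through biotite; chain identifiers map to strand
indices and the builder stores the layer index in the B-factor column
(recovered on read when the column holds non-negative integers, left
unset otherwise).  XYZ is the plain count/comment/element-x-y-z text
format, one block per frame.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ParseError, SelectionError, StructureError, WindowError
from .structures import FibrilStructure, Trajectory

_CHAIN_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                   "abcdefghijklmnopqrstuvwxyz0123456789")


def _locate_bad_pdb_line(path: Path) -> int | None:
    """Line number of the first ATOM/HETATM record with a malformed coordinate."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        try:
                            float(line[lo:hi])
                        except ValueError:
                            return lineno
    except OSError:
        return None
    return None


def read_pdb(path: str | Path) -> tuple[FibrilStructure, Trajectory]:
    """Read a (multi-MODEL) PDB file.

    Returns the topology of the first model plus one trajectory frame per
    MODEL (a single frame when no MODEL records exist).  Insertion codes
    are rejected; an atom-count mismatch between models is a structural
    error.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, extra_fields=["b_factor"])
    except Exception as exc:  # biotite raises mixed exception types
        lineno = _locate_bad_pdb_line(path)
        if lineno is not None:
            raise ParseError(f"{path}: malformed coordinate field at line {lineno}") from exc
        msg = str(exc)
        if "atoms" in msg or "models" in msg or "length" in msg:
            raise StructureError(f"{path}: inconsistent atom count across MODELs "
                                 f"({msg})") from exc
        raise ParseError(f"{path}: {msg}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    first = stack[0]
    if hasattr(first, "ins_code") and np.any(first.ins_code != ""):
        raise ParseError(f"{path}: insertion codes are not supported")

    chain_ids = first.chain_id
    order: dict[str, int] = {}
    for c in chain_ids:
        order.setdefault(c, len(order))
    strand_idx = np.array([order[c] for c in chain_ids])

    b = first.b_factor if "b_factor" in first.get_annotation_categories() else None
    if b is not None and np.all(np.isfinite(b)) and np.all(b >= 0) and \
            np.allclose(b, np.round(b), atol=1e-6) and np.any(b > 0):
        layer_idx = np.round(b).astype(int)
    else:
        layer_idx = np.full(first.array_length(), -1)

    structure = FibrilStructure(
        elements=np.array([e.capitalize() for e in first.element], dtype=object),
        atom_names=np.array(list(first.atom_name), dtype=object),
        residue_indices=np.asarray(first.res_id, dtype=int),
        strand_indices=strand_idx,
        layer_indices=layer_idx,
        coordinates=np.asarray(first.coord, dtype=float),
        metadata={"source": str(path)},
    )
    traj = Trajectory(frames=np.asarray(stack.coord, dtype=float),
                      structure=structure)
    return structure, traj


def write_pdb(path: str | Path, structure: FibrilStructure,
              frames: np.ndarray | None = None) -> None:
    """Write a structure (or trajectory frames) as a multi-MODEL PDB file.

    Strand indices become chain identifiers (cycled through an
    alphanumeric alphabet); the layer index is stored in the B-factor
    column.
    """
    coords = structure.coordinates[None] if frames is None else np.asarray(frames)
    if coords.ndim == 2:
        coords = coords[None]
    n = structure.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords[0], dtype=np.float32)
    atoms.chain_id = np.array(
        [_CHAIN_ALPHABET[s % len(_CHAIN_ALPHABET)] for s in structure.strand_indices])
    atoms.res_id = structure.residue_indices + 1
    atoms.res_name = np.array(["GLY"] * n)
    atoms.atom_name = np.array(list(structure.atom_names))
    atoms.element = np.array([e.upper() for e in structure.elements])
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.set_annotation("b_factor",
                         np.maximum(structure.layer_indices, 0).astype(float))
    atoms.set_annotation("occupancy", np.ones(n))
    stack = struc.stack([atoms] * len(coords))
    stack.coord = np.asarray(coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_xyz_trajectory(path: str | Path, traj: Trajectory,
                         comment: str = "fibrilmech frame") -> None:
    """Write a multi-frame XYZ file (count line, comment, element x y z)."""
    elements = traj.structure.elements
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.frames):
            fh.write(f"{traj.n_atoms}\n{comment} {i}\n")
            for e, (x, y, z) in zip(elements, frame):
                fh.write(f"{e} {x:.3f} {y:.3f} {z:.3f}\n")


def read_xyz_trajectory(path: str | Path,
                        atom_table: FibrilStructure | None = None) -> Trajectory:
    """Read a multi-frame XYZ file.

    When ``atom_table`` is given, element symbols are checked against it
    and its topology is attached to the returned trajectory; otherwise a
    minimal one-strand topology is synthesized from the element symbols.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    frames = []
    elements_seen: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: expected atom count at line {i + 1}") from exc
        block = lines[i + 2: i + 2 + count]
        if len(block) < count:
            raise ParseError(f"{path}: frame at line {i + 1} declares {count} atoms "
                             f"but only {len(block)} lines follow")
        coords = np.empty((count, 3))
        elements = []
        for k, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: malformed atom line {i + 3 + k}")
            elements.append(parts[0].capitalize())
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"{path}: malformed coordinate at line "
                                 f"{i + 3 + k}") from exc
        if elements_seen is None:
            elements_seen = elements
        elif elements != elements_seen:
            raise StructureError(f"{path}: element order changes between frames")
        frames.append(coords)
        i += 2 + count
    if not frames:
        raise ParseError(f"{path}: no frames found")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise StructureError(f"{path}: atom count varies across frames")
    if atom_table is not None:
        if atom_table.n_atoms != len(elements_seen):
            raise StructureError("atom table does not match XYZ atom count")
        if list(atom_table.elements) != elements_seen:
            raise StructureError("atom table elements do not match XYZ file")
        structure = atom_table
    else:
        n = len(elements_seen)
        structure = FibrilStructure(
            elements=np.array(elements_seen, dtype=object),
            atom_names=np.array(elements_seen, dtype=object),
            residue_indices=np.arange(n),
            strand_indices=np.zeros(n, dtype=int),
            layer_indices=np.full(n, -1),
            coordinates=frames[0],
            metadata={"source": str(path)},
        )
    return Trajectory(frames=np.array(frames), structure=structure)


def select_calpha(traj: Trajectory) -> Trajectory:
    """Restrict a trajectory to Calpha atoms (or synthetic CA beads)."""
    mask = traj.structure.atom_names == "CA"
    if not np.any(mask):
        raise SelectionError("no Calpha (CA) atoms in structure")
    if np.all(mask):
        return traj
    return traj.subset_atoms(mask)


def window_frames(traj: Trajectory, discard_fraction: float = 0.5,
                  stride: int = 1) -> Trajectory:
    """Keep the equilibrated tail of a trajectory, subsampled by ``stride``.

    Frames in the initial ``discard_fraction`` of the run are dropped
    (mirroring the common practice of analysing only the final,
    equilibrated segment); the sampling-interval metadata is scaled by the
    stride.
    """
    if not 0 <= discard_fraction < 1:
        raise WindowError("discard_fraction must be in [0, 1)")
    if stride < 1:
        raise WindowError("stride must be >= 1")
    start = int(np.ceil(traj.n_frames * discard_fraction))
    index = np.arange(start, traj.n_frames, stride)
    if index.size == 0:
        raise WindowError("windowing produced an empty trajectory")
    out = traj.subset_frames(index)
    out.time_per_frame = traj.time_per_frame * stride
    return out
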