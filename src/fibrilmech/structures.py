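"""Core in-memory containers: fibril topology and coordinate trajectories.

A :class:`FibrilStructure` is a flat atom table with strand/layer topology
(the strand is a single beta-peptide chain, the layer is one rung of the
cross-beta stack).  A :class:`Trajectory` is an ordered stack of coordinate
frames sharing one atom table; it is the universal input of the analysis
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StructureError

#: Standard atomic masses [Da] for the elements the package produces/reads.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

#: Van der Waals radii [A] (Bondi set), used for SASA and envelope sections.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}


def element_mass(element: str) -> float:
    return ELEMENT_MASSES.get(element.capitalize(), 12.011)


def element_radius(element: str) -> float:
    return VDW_RADII.get(element.capitalize(), 1.70)


@dataclass
class FibrilStructure:
    """Atom table with strand/layer topology.

    Parameters
    ----------
    elements, atom_names
        Per-atom element symbol and atom name (``CA``, ``N``, ...).
    residue_indices
        0-based residue index within the strand.
    strand_indices
        0-based global strand index.
    layer_indices
        0-based layer index, or ``-1`` when unknown.
    coordinates
        Reference coordinates, shape ``(n_atoms, 3)`` [A].
    masses
        Per-atom masses [Da]; derived from the element when omitted.
    """

    elements: np.ndarray
    atom_names: np.ndarray
    residue_indices: np.ndarray
    strand_indices: np.ndarray
    layer_indices: np.ndarray
    coordinates: np.ndarray
    masses: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.strand_indices = np.asarray(self.strand_indices, dtype=int)
        self.layer_indices = np.asarray(self.layer_indices, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.elements)
        if self.coordinates.shape != (n, 3):
            raise StructureError(
                f"coordinates shape {self.coordinates.shape} != ({n}, 3)"
            )
        for name in ("atom_names", "residue_indices", "strand_indices", "layer_indices"):
            if len(getattr(self, name)) != n:
                raise StructureError(f"{name} length mismatch")
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("non-finite coordinates")
        if self.masses is None:
            self.masses = np.array([element_mass(e) for e in self.elements])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if len(self.masses) != n:
                raise StructureError("masses length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_strands(self) -> int:
        return len(np.unique(self.strand_indices))

    @property
    def n_layers(self) -> int:
        known = self.layer_indices[self.layer_indices >= 0]
        return len(np.unique(known)) if known.size else 0

    @property
    def total_mass(self) -> float:
        """Total mass [Da]."""
        return float(self.masses.sum())

    def subset(self, mask: np.ndarray) -> "FibrilStructure":
        mask = np.asarray(mask)
        return FibrilStructure(
            elements=self.elements[mask],
            atom_names=self.atom_names[mask],
            residue_indices=self.residue_indices[mask],
            strand_indices=self.strand_indices[mask],
            layer_indices=self.layer_indices[mask],
            coordinates=self.coordinates[mask],
            masses=self.masses[mask],
            metadata=dict(self.metadata),
        )

    def vdw_radii(self) -> np.ndarray:
        return np.array([element_radius(e) for e in self.elements])


@dataclass
class Trajectory:
    """Ordered coordinate frames over a shared atom table.

    ``frames`` has shape ``(n_frames, n_atoms, 3)`` [A]; ``time_per_frame``
    is the sampling interval [ps].
    """

    frames: np.ndarray
    structure: FibrilStructure
    time_per_frame: float = 6.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} != structure atom count "
                f"{self.structure.n_atoms}"
            )
        if self.time_per_frame <= 0:
            raise StructureError("time_per_frame must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise StructureError("non-finite frame coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def subset_atoms(self, mask: np.ndarray) -> "Trajectory":
        mask = np.asarray(mask)
        return Trajectory(
            frames=self.frames[:, mask, :],
            structure=self.structure.subset(mask),
            time_per_frame=self.time_per_frame,
        )

    def subset_frames(self, index: np.ndarray) -> "Trajectory":
        return Trajectory(
            frames=self.frames[index],
            structure=self.structure,
            time_per_frame=self.time_per_frame,
        )
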