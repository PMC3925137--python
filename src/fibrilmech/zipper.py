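"""Steric-zipper polymorph taxonomy and an idealized cross-beta fibril builder.

An amyloid steric zipper is the dry interface between two paired beta
sheets.  Three binary choices classify the packing: whether the two sheets
are co-aligned or anti-aligned (ladder alignment), whether strands within a
sheet stack parallel or anti-parallel (hydrogen-bond type), and whether the
two mating sheet faces are equivalent (homo) or distinct (hetero zipper).
The eight combinations are the canonical polymorph classes.

The builder produces an idealized cross-beta geometry: layers of beta
strands stacked with a ~4.8 A rise and a small per-layer twist about the
fibril axis, one strand per sheet per layer.  It is a geometric stand-in
for experimentally derived fibril models, with known ground truth (exact
twist, straight axis) so that the geometry metrics can be validated
against construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GeometryError
from .structures import FibrilStructure

#: Canonical beta-strand Calpha-Calpha spacing along the strand [A].
CA_SPACING = 3.4

# Idealized backbone offsets [A]: N and C sit on the midpoints between
# consecutive Calpha positions; the carbonyl O points along +fibril axis and
# the amide H along -axis so that ladder hydrogen bonds run parallel to the
# axis (as in a cross-beta sheet).  The O offset is chosen to put the
# donor-acceptor distance at 3.4 A for the canonical 4.8 A rise.
_N_SHIFT = -1.7
_C_SHIFT = 1.7
_O_RISE = 1.40
_H_DROP = 1.02


@dataclass(frozen=True)
class ZipperClass:
    """One steric-zipper polymorph class."""

    class_id: int
    abbreviation: str
    ladder_alignment: str  # "co-aligned" | "anti-aligned"
    hbond_type: str  # "parallel" | "anti-parallel"
    zipper_type: str  # "homo" | "hetero"

    @property
    def is_anti_aligned(self) -> bool:
        return self.ladder_alignment == "anti-aligned"

    @property
    def is_antiparallel(self) -> bool:
        return self.hbond_type == "anti-parallel"


_ZIPPER_TABLE = [
    (1, "co-pho", "co-aligned", "parallel", "homo"),
    (2, "co-phe", "co-aligned", "parallel", "hetero"),
    (3, "aa-pho", "anti-aligned", "parallel", "homo"),
    (4, "aa-phe", "anti-aligned", "parallel", "hetero"),
    (5, "co-apho", "co-aligned", "anti-parallel", "homo"),
    (6, "co-aphe", "co-aligned", "anti-parallel", "hetero"),
    (7, "aa-apho", "anti-aligned", "anti-parallel", "homo"),
    (8, "aa-aphe", "anti-aligned", "anti-parallel", "hetero"),
]


def enumerate_zipper_classes() -> list[ZipperClass]:
    """Return the eight steric-zipper polymorph classes, in canonical order."""
    return [ZipperClass(*row) for row in _ZIPPER_TABLE]


def zipper_class(key: int | str) -> ZipperClass:
    """Look a class up by id (1-8) or abbreviation (e.g. ``"aa-apho"``)."""
    for cls in enumerate_zipper_classes():
        if key in (cls.class_id, cls.abbreviation):
            return cls
    raise KeyError(f"unknown zipper class {key!r}")


@dataclass
class FibrilBuildParams:
    """Geometry parameters for the idealized fibril builder.

    ``twist_per_layer`` is the rotation [deg] between successive layers
    about the fibril axis; ``per_layer_twist`` optionally overrides it with
    one value per layer gap (used to inject twist disorder).
    """

    n_layers: int = 6
    strands_per_layer: int = 2
    rise_per_layer: float = 4.8
    twist_per_layer: float = 0.0
    residues_per_strand: int = 9
    sheet_separation: float = 10.0
    include_backbone_atoms: bool = False
    per_layer_twist: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.rise_per_layer <= 0:
            raise ValueError("rise_per_layer must be positive")
        if not 0 <= self.twist_per_layer < 180:
            raise ValueError("twist_per_layer must be in [0, 180)")
        if self.strands_per_layer < 1:
            raise ValueError("strands_per_layer must be >= 1")
        if self.residues_per_strand < 2:
            raise ValueError("residues_per_strand must be >= 2")
        if self.per_layer_twist is not None and len(self.per_layer_twist) != self.n_layers - 1:
            raise ValueError("per_layer_twist must have n_layers - 1 entries")


def _rotation_about_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_zipper_fibril(zipper: ZipperClass, params: FibrilBuildParams) -> FibrilStructure:
    """Build an idealized steric-zipper fibril.

    The fibril axis is z.  Sheets are offset along x by ``sheet_separation``;
    strands run along +/-y.  Anti-aligned classes reverse the strand
    direction between the two sheets; anti-parallel hydrogen bonding
    reverses it between successive layers within a sheet.  Layer ``k`` is
    the base layer translated by ``k * rise_per_layer`` along z and rotated
    by the cumulative twist about the axis.

    With ``include_backbone_atoms`` each residue carries N, H, CA, C, O in
    an idealized extended-strand geometry whose ladder hydrogen bonds run
    parallel to the fibril axis.
    """
    if zipper.zipper_type == "hetero" and params.strands_per_layer != 2:
        raise GeometryError(
            "hetero zipper classes require exactly 2 strands per layer "
            "(two distinct sheet faces)"
        )

    n_res = params.residues_per_strand
    n_sheets = params.strands_per_layer
    gaps = (
        np.asarray(params.per_layer_twist, dtype=float)
        if params.per_layer_twist is not None
        else np.full(params.n_layers - 1, params.twist_per_layer)
    )
    cumulative_twist = np.concatenate([[0.0], np.cumsum(gaps)])

    # residue grid centered on the strand midpoint
    t = (np.arange(n_res) - (n_res - 1) / 2.0) * CA_SPACING

    elements, names, res_idx, strand_idx, layer_idx, coords = [], [], [], [], [], []
    for layer in range(params.n_layers):
        rot = _rotation_about_z(cumulative_twist[layer])
        z0 = layer * params.rise_per_layer
        for sheet in range(n_sheets):
            x0 = (sheet - (n_sheets - 1) / 2.0) * params.sheet_separation
            direction = 1.0
            if zipper.is_anti_aligned and sheet % 2 == 1:
                direction *= -1.0
            if zipper.is_antiparallel and layer % 2 == 1:
                direction *= -1.0
            strand = layer * n_sheets + sheet
            for i in range(n_res):
                y_ca = direction * t[i]
                ca = np.array([x0, y_ca, 0.0])
                atoms = [("C", "CA", ca)]
                if params.include_backbone_atoms:
                    n_pos = np.array([x0, y_ca + direction * _N_SHIFT, 0.0])
                    c_pos = np.array([x0, y_ca + direction * _C_SHIFT, 0.0])
                    o_pos = c_pos + np.array([0.0, 0.0, _O_RISE])
                    h_pos = n_pos + np.array([0.0, 0.0, -_H_DROP])
                    atoms = [
                        ("N", "N", n_pos),
                        ("H", "H", h_pos),
                        ("C", "CA", ca),
                        ("C", "C", c_pos),
                        ("O", "O", o_pos),
                    ]
                for element, name, pos in atoms:
                    elements.append(element)
                    names.append(name)
                    res_idx.append(i)
                    strand_idx.append(strand)
                    layer_idx.append(layer)
                    coords.append(rot @ pos + np.array([0.0, 0.0, z0]))

    structure = FibrilStructure(
        elements=np.array(elements, dtype=object),
        atom_names=np.array(names, dtype=object),
        residue_indices=np.array(res_idx),
        strand_indices=np.array(strand_idx),
        layer_indices=np.array(layer_idx),
        coordinates=np.array(coords),
        metadata={
            "zipper_class": zipper.abbreviation,
            "n_layers": params.n_layers,
            "strands_per_layer": params.strands_per_layer,
            "twist_per_layer": params.twist_per_layer,
            "rise_per_layer": params.rise_per_layer,
        },
    )
    return structure
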