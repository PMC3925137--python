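"""Conformational and interaction metrics of fluctuating fibrils.

RMSD after least-squares superposition, inter-layer twist (dihedral)
angles, the bending angle of the fibril axis, the twist-disorder order
parameter with its 0.07 instability threshold, strands per helical pitch,
geometric hydrogen-bond detection, Shrake-Rupley solvent-accessible
surface area and the SASA-proportional nonpolar solvation energy
``dG_np = gamma * SASA + beta`` (gamma = 0.00542 kcal/mol/A^2,
beta = 0.92 kcal/mol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, SelectionError
from .structures import FibrilStructure, Trajectory

logger = logging.getLogger(__name__)

#: Default order-parameter instability threshold (rad^2): fibrils with a
#: larger twist-disorder variance are flagged unstable/disordered.
OP_THRESHOLD = 0.07


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch), mobile -> reference.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile coordinates onto the
    reference frame.  The rotation is proper (det = +1); a reflection-only
    optimum is corrected by flipping the smallest singular direction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("coordinate sets must both be (n, 3)")
    n = len(mobile)
    if n < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def rmsd_series(traj: Trajectory, ref_frame_index: int = 0) -> np.ndarray:
    """Per-frame RMSD [A] after superposition onto a reference frame."""
    if not 0 <= ref_frame_index < traj.n_frames:
        raise IndexError("reference frame index out of range")
    ref = traj.frames[ref_frame_index]
    return np.array([superpose(frame, ref)[2] for frame in traj.frames])


# ---------------------------------------------------------------------------
# layer frames, dihedrals, bending angle
# ---------------------------------------------------------------------------

@dataclass
class LayerFrame:
    """Per-layer reference frame: centroid, in-plane axis, normal."""

    centroid: np.ndarray
    axis: np.ndarray
    normal: np.ndarray
    half_extent: float


def layer_frames(coords: np.ndarray, layer_ids: np.ndarray) -> list[LayerFrame]:
    """Centroid and in-plane principal axis of every layer, in layer order.

    The in-plane axis is the largest-variance principal direction of the
    layer's atoms; its sign is chained for continuity (positive dot
    product with the previous layer's axis), so twist angles between
    successive layers are well defined for both parallel and anti-parallel
    stacking.
    """
    coords = np.asarray(coords, dtype=float)
    layer_ids = np.asarray(layer_ids)
    unique = np.unique(layer_ids[layer_ids >= 0])
    if len(unique) < 2:
        raise GeometryError("need at least 2 layers")
    frames: list[LayerFrame] = []
    prev_axis = None
    for lay in unique:
        pts = coords[layer_ids == lay]
        if len(pts) < 2:
            raise GeometryError(f"layer {lay} has fewer than 2 atoms")
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        cov = centered.T @ centered / len(pts)
        evals, evecs = np.linalg.eigh(cov)
        if evals[2] < 1e-12:
            raise GeometryError(f"layer {lay} is degenerate (zero-length axis)")
        axis = evecs[:, 2]
        if prev_axis is not None and axis @ prev_axis < 0:
            axis = -axis
        elif prev_axis is None:
            i = np.argmax(np.abs(axis))
            if axis[i] < 0:
                axis = -axis
        normal = evecs[:, 0]
        normal = normal - (normal @ axis) * axis
        normal /= np.linalg.norm(normal)
        half_extent = float(np.abs(centered @ axis).max())
        frames.append(LayerFrame(centroid, axis, normal, half_extent))
        prev_axis = axis
    return frames


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> float:
    """Signed dihedral [deg] of four points, right-handed convention, (-180, 180].

    Zero for the cis (eclipsed) arrangement, per the standard torsion
    convention.
    """
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise GeometryError("degenerate dihedral: central bond has zero length")
    b1u = b1 / nb1
    v = b0 - (b0 @ b1u) * b1u
    w = b2 - (b2 @ b1u) * b1u
    if np.linalg.norm(v) < 1e-12 or np.linalg.norm(w) < 1e-12:
        raise GeometryError("degenerate dihedral: collinear points")
    x = v @ w
    y = np.cross(b1u, v) @ w
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)


def layer_dihedral(coords: np.ndarray, layer_ids: np.ndarray) -> np.ndarray:
    """Twist angle [deg] between each pair of successive layers.

    For layers j, j+1 the dihedral of (axis endpoint of j, centroid j,
    centroid j+1, axis endpoint of j+1) is returned, i.e. the rotation of
    the layer's in-plane axis about the stacking direction.
    """
    frames = layer_frames(coords, layer_ids)
    out = []
    for a, b in zip(frames[:-1], frames[1:]):
        e = max(min(a.half_extent, b.half_extent), 1e-3)
        out.append(dihedral_angle(a.centroid + e * a.axis, a.centroid,
                                  b.centroid, b.centroid + e * b.axis))
    return np.array(out)


def bending_angle(coords: np.ndarray, layer_ids: np.ndarray,
                  partition: int | None = None) -> float:
    """Deviation [deg] of the fibril axis from straight (0 = straight).

    Three layer centroids define the angle: the first layer, the
    mid-fibril layer at ``partition`` (default the middle), and the last
    layer; the reported value is 180 deg minus the angle subtended at the
    middle centroid.
    """
    coords = np.asarray(coords, dtype=float)
    layer_ids = np.asarray(layer_ids)
    unique = np.unique(layer_ids[layer_ids >= 0])
    if len(unique) < 3:
        raise GeometryError("bending angle needs at least 3 layers")
    centroids = np.array([coords[layer_ids == lay].mean(axis=0) for lay in unique])
    mid = partition if partition is not None else len(centroids) // 2
    if not 0 < mid < len(centroids) - 1:
        raise GeometryError("partition must split layers into two non-empty halves")
    v1 = centroids[0] - centroids[mid]
    v2 = centroids[-1] - centroids[mid]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise GeometryError("degenerate layer centroids")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(180.0 - np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# order parameter and helical pitch
# ---------------------------------------------------------------------------

def order_parameter(dihedrals_deg: np.ndarray) -> float:
    """Twist-disorder order parameter: variance [rad^2] of layer dihedrals.

    The population variance of the dihedral angles (radians) about their
    circular mean; 0 for a perfectly uniform twist, larger for disordered
    stacking.  Structures with OP > 0.07 are conventionally flagged
    unstable/disordered.
    """
    phi = np.deg2rad(np.asarray(dihedrals_deg, dtype=float))
    if phi.size < 2:
        raise GeometryError("order parameter needs at least 2 dihedrals")
    # wrap deviations about the circular mean (robust near +/-180), then take
    # the ordinary two-pass population variance of the wrapped values
    circ_mean = np.arctan2(np.sin(phi).mean(), np.cos(phi).mean())
    dev = np.angle(np.exp(1j * (phi - circ_mean)))
    dev = dev - dev.mean()
    return float(np.mean(dev ** 2))


def circular_std_op(dihedrals_deg: np.ndarray) -> float:
    """Alternative order parameter: circular standard deviation [rad]."""
    phi = np.deg2rad(np.asarray(dihedrals_deg, dtype=float))
    if phi.size < 2:
        raise GeometryError("order parameter needs at least 2 dihedrals")
    r = np.abs(np.exp(1j * phi).mean())
    r = min(r, 1.0)
    return float(np.sqrt(-2.0 * np.log(max(r, 1e-300))))


OP_VARIANTS = {"variance": order_parameter, "circular-std": circular_std_op}


def is_disordered(op_value: float, threshold: float = OP_THRESHOLD) -> bool:
    """Instability flag: OP above the disorder threshold."""
    return op_value > threshold


def strands_per_pitch(mean_dihedral_deg: float, strands_per_layer: int = 2) -> int:
    """Number of beta strands forming one full helical turn.

    ``strands_per_layer * round(360 / |mean dihedral|)``; e.g. a 10 deg
    inter-layer twist with 2 strands per layer gives 72 strands per pitch.
    """
    if not 0 < mean_dihedral_deg <= 360:
        raise GeometryError("mean dihedral must be in (0, 360] degrees")
    if strands_per_layer < 1:
        raise GeometryError("strands_per_layer must be >= 1")
    return int(strands_per_layer * round(360.0 / mean_dihedral_deg))


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HBond:
    """One detected hydrogen bond (backbone N-H...O=C)."""

    donor: int
    hydrogen: int | None
    acceptor: int
    distance: float  # D...A, A
    angle: float | None  # D-H...A, deg


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    With hydrogens: D...A <= ``distance_cutoff`` and D-H...A >=
    ``angle_cutoff``.  Without hydrogens a distance-only N...O criterion
    at ``distance_only_cutoff`` is used (logged once).
    """

    distance_cutoff: float = 3.5  # A
    angle_cutoff: float = 150.0  # deg
    distance_only_cutoff: float = 3.2  # A


def _attach_hydrogens(structure: FibrilStructure, donors: np.ndarray,
                      coords: np.ndarray) -> dict[int, int]:
    """Map donor atom index -> covalently attached hydrogen index (<= 1.3 A)."""
    h_idx = np.flatnonzero(structure.elements == "H")
    attached: dict[int, int] = {}
    if h_idx.size == 0:
        return attached
    tree = cKDTree(coords[h_idx])
    for d in donors:
        near = tree.query_ball_point(coords[d], 1.3)
        if near:
            attached[d] = int(h_idx[near[0]])
    return attached


def detect_hbonds(structure: FibrilStructure, coords: np.ndarray | None = None,
                  criteria: HBondCriteria | None = None) -> list[HBond]:
    """Detect backbone hydrogen bonds by geometric criterion.

    Donors are backbone nitrogens (with their attached hydrogen when
    present), acceptors are carbonyl/carboxyl oxygens.  Pairs within the
    same strand closer than two residues apart are excluded (covalently
    constrained neighbours, not hydrogen bonds).
    """
    criteria = criteria or HBondCriteria()
    coords = structure.coordinates if coords is None else np.asarray(coords, float)
    donors = np.flatnonzero(structure.atom_names == "N")
    acceptors = np.flatnonzero(structure.atom_names == "O")
    if donors.size == 0 or acceptors.size == 0:
        return []
    hydrogens = _attach_hydrogens(structure, donors, coords)
    have_h = len(hydrogens) > 0
    if not have_h:
        logger.warning("no hydrogens found: falling back to N...O distance-only "
                       "criterion (%.2f A)", criteria.distance_only_cutoff)
    cutoff = criteria.distance_cutoff if have_h else criteria.distance_only_cutoff
    tree = cKDTree(coords[acceptors])
    bonds: list[HBond] = []
    for d in donors:
        for k in tree.query_ball_point(coords[d], cutoff):
            a = int(acceptors[k])
            if (structure.strand_indices[d] == structure.strand_indices[a]
                    and abs(int(structure.residue_indices[d])
                            - int(structure.residue_indices[a])) <= 1):
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            if have_h:
                h = hydrogens.get(int(d))
                if h is None:
                    continue
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom < 1e-12:
                    continue
                ang = float(np.degrees(np.arccos(
                    np.clip(v1 @ v2 / denom, -1.0, 1.0))))
                if ang >= criteria.angle_cutoff:
                    bonds.append(HBond(int(d), h, a, dist, ang))
            else:
                bonds.append(HBond(int(d), None, a, dist, None))
    return bonds


def hbonds_per_residue(traj: Trajectory, criteria: HBondCriteria | None = None
                       ) -> np.ndarray:
    """Per-frame hydrogen-bond count divided by the number of residues."""
    structure = traj.structure
    n_res = len(np.unique(
        structure.strand_indices.astype(np.int64) * 100000
        + structure.residue_indices))
    if n_res == 0:
        raise SelectionError("no residues in structure")
    return np.array([
        len(detect_hbonds(structure, frame, criteria)) / n_res
        for frame in traj.frames
    ])


# ---------------------------------------------------------------------------
# solvent-accessible surface area and nonpolar solvation
# ---------------------------------------------------------------------------

def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
         n_sphere_points: int = 960) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area [A^2].

    For each atom, test points on the sphere of radius ``r_i + probe``;
    the accessible fraction (points not buried inside any neighbour's
    expanded sphere) times ``4 pi (r_i + probe)^2`` is the per-atom area.
    Returns ``(total, per_atom)``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if n_sphere_points < 16:
        raise ValueError("n_sphere_points must be >= 16")
    if np.any(radii <= 0) or probe < 0:
        raise ValueError("radii must be positive and probe non-negative")
    n = len(coords)
    expanded = radii + probe
    sphere = _golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords)
    pairs = tree.query_ball_tree(tree, 2.0 * expanded.max())
    per_atom = np.zeros(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in pairs[i]:
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) >= expanded[i] + expanded[j]:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= expanded[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return float(per_atom.sum()), per_atom


@dataclass
class SolvationParams:
    """Linear SASA solvation model parameters."""

    gamma: float = 0.00542  # kcal/mol/A^2
    beta_const: float = 0.92  # kcal/mol
    probe_radius: float = 1.4  # A

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")


def nonpolar_solvation(sasa_value: float,
                       params: SolvationParams | None = None) -> float:
    """Nonpolar solvation energy dG_np = gamma * SASA + beta [kcal/mol]."""
    if sasa_value < 0:
        raise ValueError("SASA must be non-negative")
    params = params or SolvationParams()
    return params.gamma * sasa_value + params.beta_const
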