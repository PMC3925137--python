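"""Continuum Euler-Bernoulli beam layer.

A thermally fluctuating fibril free in solution behaves, at long
wavelengths, like a free-free elastic beam.  This module provides

* the analytic free-free bending mode shapes
  ``phi_n(x) = A_n[(cosh b x + cos b x) - sigma_n (sinh b x + sin b x)]``
  with roots of ``cos(lambda) cosh(lambda) = 1``, and the cosine shapes of
  free-free torsion/extension;
* the corresponding natural frequencies
  (bending ``omega_n = lambda_n^2 sqrt(E_B I / (mu L^4))``,
  torsion ``omega_n = (n pi / L) sqrt(G_T / rho)``,
  axial ``omega_n = (n pi / L) sqrt(E_X / rho)``);
* classification of quasi-harmonic principal modes into deformation
  families (soft/stiff bending, torsion, axial, rigid, mixed) by overlap
  with the analytic shape bases;
* inversion of measured frequencies into bending rigidity, persistence
  length ``l_p = E_B I / k_B T``, torsional shear modulus and axial
  elastic modulus;
* estimation of the cross-section (length, mass per length, area, second
  moments) from a mean structure, needed only to convert rigidities into
  moduli.

Free-free boundary conditions are used throughout: an unconstrained beam
is the only continuum model consistent with the six rigid-body zero modes
of a fibril fluctuating in solvent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .errors import GeometryError
from .units import ANGSTROM, DALTON, KB

logger = logging.getLogger(__name__)

FAMILIES = ("soft-bend", "stiff-bend", "torsion", "axial", "rigid", "mixed")


# ---------------------------------------------------------------------------
# free-free bending roots and mode shapes
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def free_free_root(n: int) -> float:
    """n-th root of the free-free characteristic equation cos(x)cosh(x) = 1.

    Solved as ``cos(x) = sech(x)`` (no overflow); the asymptotic guess
    ``(2n+1) pi / 2`` brackets every root.
    """
    if n < 1:
        raise ValueError("mode order n must be >= 1")
    guess = (2 * n + 1) * np.pi / 2.0
    return brentq(lambda x: np.cos(x) - 1.0 / np.cosh(x), guess - 0.5, guess + 0.5,
                  xtol=1e-14, rtol=1e-15)


def beam_mode_shape(n: int, x_over_l: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Free-free bending mode shape phi_n evaluated at positions x/L in [0, 1].

    ``sigma_n = (cosh l - cos l)/(sinh l - sin l)`` with ``l`` the n-th
    free-free root.  With ``normalize`` the discrete vector is scaled to
    unit Euclidean norm.
    """
    lam = free_free_root(n)
    s = np.asarray(x_over_l, dtype=float)
    if s.size and (s.min() < -1e-9 or s.max() > 1 + 1e-9):
        raise ValueError("x_over_l must lie in [0, 1]")
    sigma = (np.cosh(lam) - np.cos(lam)) / (np.sinh(lam) - np.sin(lam))
    phi = (np.cosh(lam * s) + np.cos(lam * s)
           - sigma * (np.sinh(lam * s) + np.sin(lam * s)))
    if normalize:
        norm = np.linalg.norm(phi)
        if norm > 0:
            phi = phi / norm
    return phi


def rod_mode_shape(n: int, x_over_l: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Free-free torsion/extension shape cos(n pi x / L)."""
    if n < 1:
        raise ValueError("mode order n must be >= 1")
    s = np.asarray(x_over_l, dtype=float)
    phi = np.cos(n * np.pi * s)
    if normalize:
        norm = np.linalg.norm(phi)
        if norm > 0:
            phi = phi / norm
    return phi


# ---------------------------------------------------------------------------
# geometry / property containers
# ---------------------------------------------------------------------------

@dataclass
class BeamGeometry:
    """Continuum beam geometry, SI units.

    ``moment_soft`` (I_z) <= ``moment_stiff`` (I_y) by convention; the soft
    bending plane is the one with the smaller second moment.  For the
    default uniform-density section model ``polar_moment = I_y + I_z``.
    """

    length: float  # m
    mass_per_length: float  # kg/m
    area: float  # m^2
    moment_soft: float  # m^4
    moment_stiff: float  # m^4
    polar_moment: float | None = None  # m^4

    def __post_init__(self) -> None:
        if self.polar_moment is None:
            self.polar_moment = self.moment_soft + self.moment_stiff
        for name in ("length", "mass_per_length", "area", "moment_soft",
                     "moment_stiff", "polar_moment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.moment_soft > self.moment_stiff:
            raise ValueError("moment_soft must be <= moment_stiff")

    @property
    def density(self) -> float:
        """Mass density rho = mu / A [kg/m^3]."""
        return self.mass_per_length / self.area


@dataclass
class MechanicalProperties:
    """Recovered mechanical properties with explicit units.

    Rigidities (N m^2) are the primary, section-free outputs; moduli (Pa)
    additionally assume a cross-section model.
    """

    bending_rigidity_soft: float  # N m^2
    bending_rigidity_stiff: float  # N m^2
    persistence_length: float  # m (from the soft plane)
    torsional_shear_modulus: float | None = None  # Pa
    axial_elastic_modulus: float | None = None  # Pa
    bending_modulus_soft: float | None = None  # Pa
    bending_modulus_stiff: float | None = None  # Pa
    temperature: float = 300.0  # K


@dataclass
class ModeAssignment:
    """Deformation-family label for one principal mode."""

    mode_index: int
    family: str  # one of FAMILIES
    order: int  # family order n (1st, 2nd, ...); 0 for rigid/mixed
    overlap: float  # in [0, 1]
    plane_overlaps: dict | None = None


# ---------------------------------------------------------------------------
# analytic frequencies and their inverses
# ---------------------------------------------------------------------------

def bending_frequency(rigidity: float, mass_per_length: float, length: float,
                      order: int) -> float:
    """omega_n = lambda_n^2 sqrt(E_B I / (mu L^4)) [rad/s]."""
    if min(rigidity, mass_per_length, length) <= 0:
        raise ValueError("rigidity, mass_per_length and length must be positive")
    lam = free_free_root(order)
    return lam ** 2 * np.sqrt(rigidity / (mass_per_length * length ** 4))


def torsion_frequency(shear_modulus: float, density: float, length: float,
                      order: int) -> float:
    """omega_n = (n pi / L) sqrt(G_T / rho) [rad/s]."""
    if min(shear_modulus, density, length) <= 0 or order < 1:
        raise ValueError("inputs must be positive and order >= 1")
    return (order * np.pi / length) * np.sqrt(shear_modulus / density)


def axial_frequency(elastic_modulus: float, density: float, length: float,
                    order: int) -> float:
    """omega_n = (n pi / L) sqrt(E_X / rho) [rad/s]."""
    if min(elastic_modulus, density, length) <= 0 or order < 1:
        raise ValueError("inputs must be positive and order >= 1")
    return (order * np.pi / length) * np.sqrt(elastic_modulus / density)


def analytic_frequencies(geom: BeamGeometry, family: str, order: int, *,
                         bending_modulus: float | None = None,
                         shear_modulus: float | None = None,
                         axial_modulus: float | None = None) -> float:
    """Natural frequency [rad/s] of one free-free mode of a given family."""
    if family in ("soft-bend", "stiff-bend"):
        if bending_modulus is None:
            raise ValueError("bending_modulus required for bending families")
        moment = geom.moment_soft if family == "soft-bend" else geom.moment_stiff
        return bending_frequency(bending_modulus * moment, geom.mass_per_length,
                                 geom.length, order)
    if family == "torsion":
        if shear_modulus is None:
            raise ValueError("shear_modulus required for torsion")
        return torsion_frequency(shear_modulus, geom.density, geom.length, order)
    if family == "axial":
        if axial_modulus is None:
            raise ValueError("axial_modulus required for axial family")
        return axial_frequency(axial_modulus, geom.density, geom.length, order)
    raise ValueError(f"unknown deformation family {family!r}")


def invert_bending(omega: float, geom: BeamGeometry, order: int,
                   plane: str = "soft") -> tuple[float, float]:
    """Invert a bending frequency into (rigidity [N m^2], modulus [Pa]).

    ``E_B I = omega^2 mu L^4 / lambda_n^4``; the modulus divides by the
    second moment of the matching principal plane.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    lam = free_free_root(order)
    rigidity = omega ** 2 * geom.mass_per_length * geom.length ** 4 / lam ** 4
    moment = geom.moment_soft if plane == "soft" else geom.moment_stiff
    return rigidity, rigidity / moment


def invert_torsion(omega: float, geom: BeamGeometry, order: int) -> float:
    """G_T = rho (omega L / n pi)^2 [Pa]."""
    if omega <= 0 or order < 1:
        raise ValueError("omega must be positive and order >= 1")
    return geom.density * (omega * geom.length / (order * np.pi)) ** 2


def invert_axial(omega: float, geom: BeamGeometry, order: int) -> float:
    """E_X = rho (omega L / n pi)^2 [Pa]."""
    if omega <= 0 or order < 1:
        raise ValueError("omega must be positive and order >= 1")
    return geom.density * (omega * geom.length / (order * np.pi)) ** 2


def persistence_length(rigidity: float, temperature: float) -> float:
    """l_p = E_B I / (k_B T) [m]."""
    if rigidity <= 0 or temperature <= 0:
        raise ValueError("rigidity and temperature must be positive")
    return rigidity / (KB * temperature)


# ---------------------------------------------------------------------------
# principal axes and rigid-body basis
# ---------------------------------------------------------------------------

def principal_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(axis, e1, e2): fibril axis and transverse principal directions.

    The axis is the largest-variance principal direction of the structure;
    e1/e2 diagonalize the transverse second-moment tensor (e1 = larger
    transverse extent).  Signs are fixed deterministically.  Raises
    :class:`GeometryError` for a near-spherical mass distribution.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] < 1.5 * evals[1]:
        raise GeometryError("degenerate axis: mass distribution has no clear "
                            "principal direction")
    axis = evecs[:, 2]
    e1 = evecs[:, 1]
    # deterministic signs: largest-magnitude component positive
    for v in (axis, e1):
        i = np.argmax(np.abs(v))
        if v[i] < 0:
            v *= -1
    e2 = np.cross(axis, e1)
    return axis, e1, e2


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal 3N x 6 basis of rigid translations/rotations about the centroid."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    centered = coords - coords.mean(axis=0)
    basis = np.zeros((3 * n, 6))
    for k in range(3):
        basis[k::3, k] = 1.0
    for k, ax in enumerate(np.eye(3)):
        disp = np.cross(np.broadcast_to(ax, centered.shape), centered)
        basis[:, 3 + k] = disp.reshape(-1)
    q, _ = np.linalg.qr(basis)
    return q


def project_out(vectors: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Remove the components of ``vectors`` (columns) lying in ``basis`` (orthonormal columns)."""
    return vectors - basis @ (basis.T @ vectors)


# ---------------------------------------------------------------------------
# mode classification
# ---------------------------------------------------------------------------

def _station_layout(coords, axis, stations):
    """Per-atom station ids, normalized axial positions and transverse offsets."""
    proj = coords @ axis
    if stations is None:
        stations = np.arange(len(coords))
    stations = np.asarray(stations, dtype=int)
    unique = np.unique(stations)
    x_station = np.array([proj[stations == s].mean() for s in unique])
    order = np.argsort(x_station)
    unique, x_station = unique[order], x_station[order]
    span = x_station.max() - x_station.min()
    if span <= 0:
        raise GeometryError("stations have no axial extent")
    s_norm = (x_station - x_station.min()) / span
    remap = {u: i for i, u in enumerate(unique)}
    atom_station = np.array([remap[s] for s in stations])
    centers = np.zeros((len(unique), 3))
    for i in range(len(unique)):
        centers[i] = coords[atom_station == i].mean(axis=0)
    offsets = coords - centers[atom_station]
    offsets -= np.outer(offsets @ axis, axis)  # transverse part only
    return atom_station, s_norm, offsets


def _family_basis(family, coords, axis, e1, e2, atom_station, s_norm, offsets,
                  max_order, rigid):
    """3N x max_order matrix of analytic family shape vectors (rigid-projected, unit norm)."""
    n = len(coords)
    cols = []
    for order in range(1, max_order + 1):
        if family in ("bend-1", "bend-2"):
            shape = beam_mode_shape(order, s_norm, normalize=False)
            direction = e1 if family == "bend-1" else e2
            disp = shape[atom_station][:, None] * direction[None, :]
        elif family == "axial":
            shape = rod_mode_shape(order, s_norm, normalize=False)
            disp = shape[atom_station][:, None] * axis[None, :]
        elif family == "torsion":
            shape = rod_mode_shape(order, s_norm, normalize=False)
            tangential = np.cross(np.broadcast_to(axis, (n, 3)), offsets)
            disp = shape[atom_station][:, None] * tangential
        else:
            raise ValueError(family)
        vec = disp.reshape(-1)
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            continue  # e.g. torsion on a pure-centerline structure
        cols.append(vec / norm)
    if not cols:
        return np.zeros((3 * n, 0))
    mat = project_out(np.column_stack(cols), rigid)
    # orthonormalize within the family for a well-defined subspace overlap
    q, r = np.linalg.qr(mat)
    keep = np.abs(np.diag(r)) > 1e-8
    return q[:, keep]


def classify_modes(eigenvectors: np.ndarray, eigenvalues: np.ndarray,
                   coords: np.ndarray, stations: np.ndarray | None = None,
                   n_modes: int | None = None, max_order: int = 4,
                   mixed_threshold: float = 0.5) -> list[ModeAssignment]:
    """Assign deformation families to principal modes by analytic-shape overlap.

    Each eigenvector (column of ``eigenvectors``, matching descending
    ``eigenvalues``) is decomposed onto the rigid-body space and the four
    analytic family subspaces (two transverse bending planes, torsion,
    axial) evaluated at the atom stations of the mean structure ``coords``
    [A].  The family with the largest squared overlap wins; modes whose
    best overlap is below ``mixed_threshold`` are labelled ``mixed``.
    The bending plane whose order-1 mode carries the larger fluctuation
    variance (lower quasi-harmonic frequency) is labelled ``soft-bend``.
    """
    coords = np.asarray(coords, dtype=float)
    axis, e1, e2 = principal_axes(coords)
    atom_station, s_norm, offsets = _station_layout(coords, axis, stations)
    rigid = rigid_body_basis(coords)
    bases = {
        family: _family_basis(family, coords, axis, e1, e2, atom_station,
                              s_norm, offsets, max_order, rigid)
        for family in ("bend-1", "bend-2", "torsion", "axial")
    }

    n_total = eigenvectors.shape[1]
    if n_modes is None:
        n_modes = min(n_total, 6 + 6 * max_order)
    assignments: list[ModeAssignment] = []
    for j in range(min(n_modes, n_total)):
        v = eigenvectors[:, j]
        scores = {}
        per_order = {}
        for family, basis in bases.items():
            if basis.shape[1] == 0:
                scores[family] = 0.0
                per_order[family] = np.zeros(0)
            else:
                comp = basis.T @ v
                scores[family] = float(comp @ comp)
                per_order[family] = comp ** 2
        rigid_score = float(np.sum((rigid.T @ v) ** 2))
        bend_score = scores["bend-1"] + scores["bend-2"]
        candidates = {"bend": bend_score, "torsion": scores["torsion"],
                      "axial": scores["axial"], "rigid": rigid_score}
        best = max(candidates, key=candidates.get)
        overlap = candidates[best]
        if overlap < mixed_threshold:
            assignments.append(ModeAssignment(j, "mixed", 0, overlap, scores))
            continue
        if best == "rigid":
            assignments.append(ModeAssignment(j, "rigid", 0, overlap, scores))
            continue
        if best == "bend":
            plane = "bend-1" if scores["bend-1"] >= scores["bend-2"] else "bend-2"
            order = int(np.argmax(per_order[plane])) + 1
            assignments.append(ModeAssignment(j, plane, order, overlap, scores))
        else:
            order = int(np.argmax(per_order[best])) + 1
            assignments.append(ModeAssignment(j, best, order, overlap, scores))

    _label_bending_planes(assignments, eigenvalues)
    return assignments


def _label_bending_planes(assignments: list[ModeAssignment],
                          eigenvalues: np.ndarray) -> None:
    """Rename bend-1/bend-2 to soft-/stiff-bend by order-1 fluctuation variance."""
    var = {}
    for plane in ("bend-1", "bend-2"):
        firsts = [a for a in assignments if a.family == plane and a.order == 1]
        if firsts:
            best = max(firsts, key=lambda a: a.overlap)
            var[plane] = eigenvalues[best.mode_index]
    if len(var) == 2:
        soft = max(var, key=var.get)  # larger variance = lower frequency = soft
    elif len(var) == 1:
        soft = next(iter(var))
        logger.info("only one bending plane observed; labelling it soft-bend")
    else:
        soft = "bend-1"
    mapping = {soft: "soft-bend",
               ("bend-2" if soft == "bend-1" else "bend-1"): "stiff-bend"}
    for a in assignments:
        if a.family in mapping:
            a.family = mapping[a.family]


# ---------------------------------------------------------------------------
# cross-section estimation
# ---------------------------------------------------------------------------

def _polygon_moments(xy: np.ndarray) -> tuple[float, float, float, float]:
    """(area, Ixx, Iyy, Ixy) of a closed polygon about its centroid."""
    x, y = xy[:, 0], xy[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    cx = np.sum((x + x1) * cross) / (6 * area)
    cy = np.sum((y + y1) * cross) / (6 * area)
    ixx = np.sum((y ** 2 + y * y1 + y1 ** 2) * cross) / 12.0
    iyy = np.sum((x ** 2 + x * x1 + x1 ** 2) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    sign = 1.0 if area > 0 else -1.0
    area, ixx, iyy, ixy = sign * area, sign * ixx, sign * iyy, sign * ixy
    # transfer to centroid
    ixx -= area * cy ** 2
    iyy -= area * cx ** 2
    ixy -= area * cx * cy
    return area, ixx, iyy, ixy


def estimate_cross_section(coords: np.ndarray, masses: np.ndarray,
                           model: str = "envelope",
                           stations: np.ndarray | None = None,
                           effective_radius: float = 1.7,
                           width: float | None = None,
                           height: float | None = None) -> BeamGeometry:
    """Estimate a :class:`BeamGeometry` from a mean structure.

    ``model="envelope"``: per axial station, the convex hull of the atom
    centers is inflated by ``effective_radius`` [A] (Minkowski sum with a
    disk); area and second moments are averaged over stations.
    ``model="fixed"``: a user-declared ``width`` x ``height`` [m]
    rectangular section.

    L is the extent of the structure along its principal axis and
    mu = total mass / L in both models.
    """
    from shapely.geometry import MultiPoint

    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    axis, e1, e2 = principal_axes(coords)
    proj = coords @ axis
    length = (proj.max() - proj.min()) * ANGSTROM
    if length <= 0:
        raise GeometryError("structure has no axial extent")
    mu = masses.sum() * DALTON / length

    if model == "fixed":
        if width is None or height is None:
            raise ValueError("fixed section model requires width and height [m]")
        w, h = max(width, height), min(width, height)
        area = w * h
        i_soft = h * w ** 3 / 12.0  # bending displacement along the wide direction
        i_stiff = w * h ** 3 / 12.0
        i_soft, i_stiff = min(i_soft, i_stiff), max(i_soft, i_stiff)
        return BeamGeometry(length, mu, area, i_soft, i_stiff)

    if model != "envelope":
        raise ValueError(f"unknown cross-section model {model!r}")

    atom_station, _, _ = _station_layout(coords, axis, stations)
    n_stations = atom_station.max() + 1
    if n_stations < 4:
        raise GeometryError("envelope model needs at least 4 axial stations")
    t1 = coords @ e1
    t2 = coords @ e2
    tensors = []
    areas = []
    for s in range(n_stations):
        pts = np.column_stack([t1[atom_station == s], t2[atom_station == s]])
        pts = pts - pts.mean(axis=0)
        poly = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(
            effective_radius, quad_segs=32)
        xy = np.asarray(poly.exterior.coords)
        area, ixx, iyy, ixy = _polygon_moments(xy)
        areas.append(area)
        tensors.append(np.array([[iyy, -ixy], [-ixy, ixx]]))
    area = float(np.mean(areas)) * ANGSTROM ** 2
    tensor = np.mean(tensors, axis=0)
    moments = np.linalg.eigvalsh(tensor) * ANGSTROM ** 4
    return BeamGeometry(length, mu, area, float(moments[0]), float(moments[1]))
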