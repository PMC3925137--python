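"""Equipartition sampling of a thermally fluctuating free-free elastic beam.

This is the ground-truth generator used in place of explicit-solvent MD:
a straight beam of beads with prescribed bending/torsional/axial
rigidities at temperature T, sampled frame by frame from the analytic
normal modes.  Every modal amplitude q_n is drawn from a zero-mean
Gaussian with the equipartition variance ``k_B T / (m_n omega_n^2)``
where ``omega_n`` comes from :mod:`fibrilmech.beam` and the modal mass
``m_n`` equals the bead mass (all beads share one mass and mode
displacement vectors are unit-norm, so the modal mass is exactly the bead
mass).  Torsion is made observable from coordinates alone by two tracer
beads per axial station, offset perpendicular to the axis.

Draw order for a fixed seed (documented determinism contract): first the
modal amplitude matrix (families in the order soft-bend, stiff-bend,
torsion, axial; orders ascending within each family; all frames per
mode), then the isotropic background jitter, then - only when rigid
motion is requested - per-frame rigid translations followed by rotation
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import beam
from .errors import GeometryError
from .structures import FibrilStructure, Trajectory
from .units import ANGSTROM, DALTON, KB

#: family order used for mode construction and amplitude draws
MODE_FAMILY_ORDER = ("soft-bend", "stiff-bend", "torsion", "axial")


@dataclass
class CrossSection:
    """Declared rectangular cross-section (uniform density model).

    The smaller principal second moment is the soft bending plane's.
    """

    width: float = 3.0e-9  # m
    height: float = 2.0e-9  # m

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def moment_soft(self) -> float:
        return min(self.width * self.height ** 3, self.height * self.width ** 3) / 12.0

    @property
    def moment_stiff(self) -> float:
        return max(self.width * self.height ** 3, self.height * self.width ** 3) / 12.0

    @property
    def polar_moment(self) -> float:
        return self.moment_soft + self.moment_stiff


@dataclass
class BeamSpec:
    """Ground-truth beam parameters (SI units).

    ``n_beads`` counts axial stations; each station carries one centerline
    bead and two torsion tracer beads at ``tracer_offset`` so the total
    atom count is ``3 * n_beads``.  ``background_rms`` is a small
    isotropic positional jitter [A] standing in for the unresolved
    high-frequency modes of a real fibril; it scales as sqrt(T / 300 K).
    """

    length: float = 12.0e-9  # m
    n_beads: int = 20  # axial stations
    mass_per_bead: float = 800.0  # Da
    bending_rigidity_soft: float = 1.0e-28  # N m^2
    bending_rigidity_stiff: float = 2.0e-28  # N m^2
    torsional_rigidity: float = 1.3e-27  # G_T * J, N m^2
    axial_stiffness: float = 3.0e-9  # E_X * A, N
    temperature: float = 300.0  # K
    n_modes_per_family: int = 4
    section: CrossSection = field(default_factory=CrossSection)
    tracer_offset: float = 1.0e-9  # m
    background_rms: float = 0.3  # A at 300 K

    def __post_init__(self) -> None:
        if self.n_beads < 8:
            raise ValueError("n_beads must be >= 8 to resolve the first two "
                             "bending shapes")
        for name in ("length", "mass_per_bead", "bending_rigidity_soft",
                     "bending_rigidity_stiff", "torsional_rigidity",
                     "axial_stiffness", "tracer_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bending_rigidity_soft > self.bending_rigidity_stiff:
            raise ValueError("bending_rigidity_soft must be <= bending_rigidity_stiff")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.n_modes_per_family < 1:
            raise ValueError("n_modes_per_family must be >= 1")

    # -- derived quantities -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return 3 * self.n_beads

    @property
    def mass_per_length(self) -> float:
        """mu = total mass / L [kg/m]."""
        return self.n_atoms * self.mass_per_bead * DALTON / self.length

    @property
    def density(self) -> float:
        """rho = mu / A [kg/m^3] of the declared uniform-density section."""
        return self.mass_per_length / self.section.area

    @property
    def torsional_shear_modulus(self) -> float:
        """G_T = (G_T J) / J [Pa]."""
        return self.torsional_rigidity / self.section.polar_moment

    @property
    def axial_elastic_modulus(self) -> float:
        """E_X = (E_X A) / A [Pa]."""
        return self.axial_stiffness / self.section.area

    def geometry(self) -> beam.BeamGeometry:
        return beam.BeamGeometry(
            length=self.length,
            mass_per_length=self.mass_per_length,
            area=self.section.area,
            moment_soft=self.section.moment_soft,
            moment_stiff=self.section.moment_stiff,
            polar_moment=self.section.polar_moment,
        )

    def mode_frequencies(self) -> list[tuple[str, int, float]]:
        """(family, order, omega [rad/s]) in the documented draw order."""
        out = []
        for family in MODE_FAMILY_ORDER:
            for order in range(1, self.n_modes_per_family + 1):
                if family == "soft-bend":
                    w = beam.bending_frequency(self.bending_rigidity_soft,
                                               self.mass_per_length,
                                               self.length, order)
                elif family == "stiff-bend":
                    w = beam.bending_frequency(self.bending_rigidity_stiff,
                                               self.mass_per_length,
                                               self.length, order)
                elif family == "torsion":
                    w = beam.torsion_frequency(self.torsional_shear_modulus,
                                               self.density, self.length, order)
                else:
                    w = beam.axial_frequency(self.axial_elastic_modulus,
                                             self.density, self.length, order)
                out.append((family, order, w))
        return out


def reference_structure(spec: BeamSpec) -> FibrilStructure:
    """Straight-beam bead geometry: centerline + two tracers per station.

    The beam axis is z, the soft bending displacement direction is x (the
    tracer offset direction), the stiff one is y.  All beads are named
    ``CA`` and share one mass so that the quasi-harmonic mass convention
    is exact.
    """
    s = spec.n_beads
    z = np.linspace(0.0, spec.length / ANGSTROM, s)
    r0 = spec.tracer_offset / ANGSTROM
    coords = np.zeros((3 * s, 3))
    strand = np.zeros(3 * s, dtype=int)
    layer = np.zeros(3 * s, dtype=int)
    res = np.zeros(3 * s, dtype=int)
    for k in range(s):
        coords[3 * k] = (0.0, 0.0, z[k])
        coords[3 * k + 1] = (r0, 0.0, z[k])
        coords[3 * k + 2] = (-r0, 0.0, z[k])
        strand[3 * k: 3 * k + 3] = (0, 1, 2)
        layer[3 * k: 3 * k + 3] = k
        res[3 * k: 3 * k + 3] = k
    return FibrilStructure(
        elements=np.array(["C"] * 3 * s, dtype=object),
        atom_names=np.array(["CA"] * 3 * s, dtype=object),
        residue_indices=res,
        strand_indices=strand,
        layer_indices=layer,
        coordinates=coords,
        masses=np.full(3 * s, spec.mass_per_bead),
        metadata={"kind": "beam", "n_layers": s, "strands_per_layer": 3},
    )


def mode_displacement_matrix(spec: BeamSpec) -> tuple[np.ndarray, list[tuple[str, int, float]]]:
    """Orthonormal, rigid-projected mode displacement vectors (3N x M) in A-space.

    Columns follow the documented family/order draw order.  Bending
    displaces every bead of a station along x (soft) or y (stiff); axial
    modes displace along z; torsion displaces the tracers tangentially
    (+/- r0 * theta along y for the +/- x tracers).
    """
    structure = reference_structure(spec)
    coords = structure.coordinates
    s_norm = np.linspace(0.0, 1.0, spec.n_beads)
    rigid = beam.rigid_body_basis(coords)
    freqs = spec.mode_frequencies()
    n_atoms = structure.n_atoms
    cols = []
    for family, order, _ in freqs:
        disp = np.zeros((n_atoms, 3))
        if family in ("soft-bend", "stiff-bend"):
            shape = beam.beam_mode_shape(order, s_norm, normalize=False)
            comp = 0 if family == "soft-bend" else 1
            for k in range(spec.n_beads):
                disp[3 * k: 3 * k + 3, comp] = shape[k]
        elif family == "axial":
            shape = beam.rod_mode_shape(order, s_norm, normalize=False)
            for k in range(spec.n_beads):
                disp[3 * k: 3 * k + 3, 2] = shape[k]
        else:  # torsion: twist angle theta_n(x); tracers move tangentially
            shape = beam.rod_mode_shape(order, s_norm, normalize=False)
            for k in range(spec.n_beads):
                disp[3 * k + 1, 1] = shape[k]
                disp[3 * k + 2, 1] = -shape[k]
        vec = disp.reshape(-1)
        cols.append(vec)
    mat = np.column_stack(cols)
    mat = beam.project_out(mat, rigid)
    # orthonormalize in construction order: cross-family overlaps vanish by
    # symmetry, so QR only removes the within-family non-orthogonality of the
    # discretely sampled shapes and each column stays dominated by its shape
    q, r = np.linalg.qr(mat)
    diag = np.diag(r)
    if np.any(np.abs(diag) < 1e-10):
        raise GeometryError("degenerate mode displacement vector")
    q = q * np.sign(diag)[None, :]
    return q, freqs


def _random_rotations(rotvecs: np.ndarray) -> np.ndarray:
    """Rotation matrices from rotation vectors, shape (F, 3) -> (F, 3, 3)."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(rotvecs).as_matrix()


def sample_beam_trajectory(spec: BeamSpec, n_frames: int, seed: int,
                           include_rigid_motion: bool = False,
                           rigid_translation_rms: float = 3.0,
                           rigid_rotation_rms: float = 0.05,
                           time_per_frame: float = 6.0) -> Trajectory:
    """Sample an equilibrium thermal trajectory of the beam.

    Each frame is the straight reference geometry plus an independent
    equipartition draw of every analytic mode amplitude, plus the
    background jitter; with ``include_rigid_motion`` a random rigid
    rotation (``rigid_rotation_rms`` [rad] per axis) about the centroid
    and translation (``rigid_translation_rms`` [A] per axis) is applied
    on top.  Deterministic for a fixed seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    structure = reference_structure(spec)
    modes, freqs = mode_displacement_matrix(spec)
    omegas = np.array([w for _, _, w in freqs])
    if np.any(omegas <= 0):
        raise GeometryError("non-positive analytic frequency")

    kbt = KB * spec.temperature
    mass_kg = spec.mass_per_bead * DALTON
    sigma_m = np.sqrt(kbt / (mass_kg * omegas ** 2))  # modal std [m]
    sigma_a = sigma_m / ANGSTROM

    rng = np.random.default_rng(seed)
    amplitudes = rng.standard_normal((len(freqs), n_frames)) * sigma_a[:, None]
    displacements = (modes @ amplitudes).T.reshape(n_frames, structure.n_atoms, 3)

    jitter_rms = spec.background_rms * np.sqrt(spec.temperature / 300.0)
    jitter = rng.standard_normal((n_frames, structure.n_atoms, 3)) * jitter_rms

    frames = structure.coordinates[None, :, :] + displacements + jitter

    if include_rigid_motion:
        translations = rng.standard_normal((n_frames, 3)) * rigid_translation_rms
        rotvecs = rng.standard_normal((n_frames, 3)) * rigid_rotation_rms
        rots = _random_rotations(rotvecs)
        centroid = structure.coordinates.mean(axis=0)
        frames = np.einsum("fij,faj->fai", rots, frames - centroid) + centroid
        frames = frames + translations[:, None, :]

    return Trajectory(frames=frames, structure=structure,
                      time_per_frame=time_per_frame)


# ---------------------------------------------------------------------------
# BeamSpec sidecar serialization
# ---------------------------------------------------------------------------

def save_beam_spec(spec: BeamSpec, path: str | Path) -> None:
    """Write the ground-truth spec as a YAML sidecar."""
    data = asdict(spec)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_beam_spec(path: str | Path) -> BeamSpec:
    data = yaml.safe_load(Path(path).read_text())
    section = CrossSection(**data.pop("section"))
    return BeamSpec(section=section, **data)
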