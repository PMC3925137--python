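"""Quasi-harmonic (principal component) analysis of Calpha fluctuations.

The fluctuation matrix ``Q = <(r - <r>) (x) (r - <r>)>`` (3N x 3N, A^2)
is accumulated over trajectory frames, optionally after iterative
least-squares superposition of every frame onto the running mean
structure.  Its spectral decomposition gives the principal modes; treating
each as an effective harmonic oscillator of mass M_C yields the
quasi-harmonic natural frequencies ``omega_j = sqrt(k_B T / (M_C xi_j))``
and the statistical-mechanics stiffness matrix
``K = k_B T sum_j xi_j^-1 v_j v_j^T`` over the retained (non-rigid) modes.

Per-mode fluctuation contributions: ``RMSF^2 = (1/N) sum xi_j`` over
retained modes, ``RMSF(k)^2 = xi_k / N`` and the dimensionless variance
fraction ``alpha_k = xi_k / sum_j xi_j`` (so ``sum alpha_k = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FibrilMechError
from .structures import Trajectory
from .units import ANGSTROM, DALTON, KB


@dataclass
class EigenSpectrum:
    """Eigendecomposition of the fluctuation matrix.

    ``eigenvalues`` xi_j [A^2] descending; ``eigenvectors`` orthonormal
    columns matching them; ``calpha_mass`` [Da] is the effective mass per
    site used by the quasi-harmonic frequency formula.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_atoms: int
    temperature: float = 300.0
    calpha_mass: float = 12.011

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if (self.eigenvectors.shape[0] != 3 * self.n_atoms
                or self.eigenvectors.shape[1] != len(self.eigenvalues)):
            raise FibrilMechError("eigenvector matrix shape mismatch")

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def retained(self, n_rigid: int = 6) -> np.ndarray:
        """Eigenvalues with the ``n_rigid`` smallest (rigid-body space) removed."""
        if n_rigid < 0 or n_rigid >= self.n_modes:
            raise ValueError("n_rigid out of range")
        return self.eigenvalues[: self.n_modes - n_rigid]


@dataclass
class ModeContribution:
    """Fluctuation budget over the retained modes."""

    alpha: np.ndarray  # variance fraction per mode, sums to 1
    rmsf_total: float  # A
    rmsf_per_mode: np.ndarray  # A


def superpose_frames(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) superposition of every frame onto ``reference``."""
    ref_centered = reference - reference.mean(axis=0)
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        mob = frame - frame.mean(axis=0)
        h = mob.T @ ref_centered
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        out[i] = mob @ r.T + reference.mean(axis=0)
    return out


def fluctuation_matrix(traj: Trajectory, align: bool = True,
                       max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Covariance of atomic displacements about the mean structure [A^2].

    With ``align`` every frame is superposed onto the mean structure,
    iterating mean and superposition to convergence (rigid diffusion is
    removed); without it the raw ensemble covariance is returned.
    """
    if traj.n_frames < 2:
        raise FibrilMechError("fluctuation matrix needs at least 2 frames")
    frames = traj.frames
    if align:
        reference = frames[0]
        for _ in range(max_iter):
            aligned = superpose_frames(frames, reference)
            new_ref = aligned.mean(axis=0)
            if np.max(np.abs(new_ref - reference)) < tol:
                reference = new_ref
                break
            reference = new_ref
        else:
            raise FibrilMechError(
                f"mean-structure alignment did not converge in {max_iter} iterations")
        frames = superpose_frames(frames, reference)
    flat = frames.reshape(traj.n_frames, -1)
    dev = flat - flat.mean(axis=0)
    return dev.T @ dev / traj.n_frames


def mean_structure(traj: Trajectory, align: bool = True,
                   max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Mean coordinates [A], after iterative superposition when ``align``."""
    frames = traj.frames
    if not align:
        return frames.mean(axis=0)
    reference = frames[0]
    for _ in range(max_iter):
        aligned = superpose_frames(frames, reference)
        new_ref = aligned.mean(axis=0)
        if np.max(np.abs(new_ref - reference)) < tol:
            return new_ref
        reference = new_ref
    return reference


def spectral_decompose(q: np.ndarray, temperature: float = 300.0,
                       calpha_mass: float = 12.011,
                       symmetry_tol: float = 1e-8) -> EigenSpectrum:
    """Full symmetric eigendecomposition of the fluctuation matrix.

    Eigenvalues are sorted descending; each eigenvector's sign is fixed so
    its largest-magnitude component is positive (deterministic output,
    first index winning ties).
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1] or q.shape[0] % 3:
        raise FibrilMechError("Q must be square with 3N rows")
    scale = max(np.abs(q).max(), 1.0)
    if np.abs(q - q.T).max() > symmetry_tol * scale:
        raise FibrilMechError("fluctuation matrix is not symmetric")
    evals, evecs = np.linalg.eigh((q + q.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    return EigenSpectrum(eigenvalues=evals, eigenvectors=evecs,
                         n_atoms=q.shape[0] // 3, temperature=temperature,
                         calpha_mass=calpha_mass)


def stiffness_matrix(spec: EigenSpectrum, n_rigid: int = 6) -> np.ndarray:
    """K = k_B T sum xi_j^-1 v_j v_j^T over retained modes [J/A^2].

    The ``n_rigid`` smallest-eigenvalue modes (the rigid-body space of an
    aligned trajectory) are excluded; any non-positive retained eigenvalue
    is an error.
    """
    xi = spec.retained(n_rigid)
    if np.any(xi <= 0):
        raise FibrilMechError("retained eigenvalues must be positive")
    v = spec.eigenvectors[:, : len(xi)]
    return KB * spec.temperature * (v / xi) @ v.T


def natural_frequencies(spec: EigenSpectrum, n_rigid: int = 0) -> np.ndarray:
    """Quasi-harmonic frequencies omega_j [rad/s] for the retained modes.

    ``omega_j = sqrt(k_B T / (M_C xi_j))`` with M_C in Da and xi in A^2;
    returned in the spectrum's mode order (ascending frequency for
    descending eigenvalue).
    """
    xi = spec.retained(n_rigid) if n_rigid else spec.eigenvalues
    if np.any(xi <= 0):
        raise FibrilMechError("non-positive eigenvalue: frequencies undefined "
                              "(exclude the rigid-body space)")
    mass_kg = spec.calpha_mass * DALTON
    return np.sqrt(KB * spec.temperature / (mass_kg * xi * ANGSTROM ** 2))


def frequencies_thz(spec: EigenSpectrum, n_rigid: int = 0) -> np.ndarray:
    """nu = omega / (2 pi) in THz."""
    return natural_frequencies(spec, n_rigid) / (2 * np.pi) / 1e12


def mode_contributions(spec: EigenSpectrum, n_rigid: int = 6,
                       variant: str = "variance-fraction") -> ModeContribution:
    """Per-mode fluctuation contributions alpha_k over the retained modes.

    ``variant="variance-fraction"`` (default): alpha_k = xi_k / sum xi,
    the squared-RMSF fraction, summing to 1.  ``variant="rmsf-ratio"``:
    the non-squared ratio RMSF(k)/RMSF.
    """
    xi = spec.retained(n_rigid)
    if len(xi) == 0:
        raise FibrilMechError("no retained modes")
    total = xi.sum()
    if total <= 0:
        raise FibrilMechError("retained spectrum has no variance")
    if variant == "variance-fraction":
        alpha = xi / total
    elif variant == "rmsf-ratio":
        alpha = np.sqrt(np.clip(xi, 0, None) / total)
    else:
        raise ValueError(f"unknown alpha variant {variant!r}")
    n = spec.n_atoms
    return ModeContribution(alpha=alpha,
                            rmsf_total=float(np.sqrt(total / n)),
                            rmsf_per_mode=np.sqrt(np.clip(xi, 0, None) / n))


def count_rigid_modes(spec: EigenSpectrum, rel_tol: float = 1e-6) -> int:
    """Number of eigenvalues below ``rel_tol`` times the largest."""
    if spec.n_modes == 0:
        raise FibrilMechError("empty spectrum")
    return int(np.sum(spec.eigenvalues < rel_tol * spec.eigenvalues[0]))


def rmsf_per_atom(traj: Trajectory, align: bool = True) -> np.ndarray:
    """Root-mean-square fluctuation per atom [A] about the mean structure."""
    frames = traj.frames
    if align:
        ref = mean_structure(traj, align=True)
        frames = superpose_frames(frames, ref)
    dev = frames - frames.mean(axis=0)
    return np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
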