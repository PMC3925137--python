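"""Shared fixtures: synthetic beam trajectories and builder fibrils.

The default beam trajectory (20 axial stations, anisotropic section,
rigidities of order 1e-28 N m^2, 300 K, 5000 frames, fixed seed) is the
study condition for the end-to-end recovery checks; it is sampled once
per session.
"""

import numpy as np
import pytest

from fibrilmech import pipeline, qha, sampler, zipper

RECOVERY_SEED = 11


@pytest.fixture(scope="session")
def beam_spec() -> sampler.BeamSpec:
    return sampler.BeamSpec()


@pytest.fixture(scope="session")
def beam_trajectory(beam_spec):
    return sampler.sample_beam_trajectory(beam_spec, n_frames=5000,
                                          seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def beam_recovery(beam_spec, beam_trajectory):
    """Full pipeline result on the reference beam trajectory."""
    return pipeline.recover_mechanics(
        beam_trajectory, geometry=beam_spec.geometry(),
        temperature=beam_spec.temperature,
        calpha_mass=beam_spec.mass_per_bead)


@pytest.fixture(scope="session")
def beam_spectrum(beam_recovery) -> qha.EigenSpectrum:
    return beam_recovery.spectrum


@pytest.fixture
def straight_fibril():
    """Untwisted 2-sheet fibril, Calpha only."""
    return zipper.build_zipper_fibril(
        zipper.zipper_class("co-pho"),
        zipper.FibrilBuildParams(n_layers=6, twist_per_layer=0.0))


@pytest.fixture
def twisted_fibril():
    """10 deg/layer twisted fibril (the canonical helical-pitch geometry)."""
    return zipper.build_zipper_fibril(
        zipper.zipper_class("co-pho"),
        zipper.FibrilBuildParams(n_layers=8, twist_per_layer=10.0))


@pytest.fixture
def backbone_fibril():
    """Fibril with idealized N/H/CA/C/O backbone atoms (H-bond ladder)."""
    return zipper.build_zipper_fibril(
        zipper.zipper_class("co-pho"),
        zipper.FibrilBuildParams(n_layers=4, include_backbone_atoms=True))


def rigid_transform(coords: np.ndarray, rotvec, translation) -> np.ndarray:
    """Apply an exact rigid rotation (about the origin) + translation."""
    from scipy.spatial.transform import Rotation

    r = Rotation.from_rotvec(rotvec).as_matrix()
    return coords @ r.T + np.asarray(translation)
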