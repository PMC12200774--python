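"""Shared fixtures: small phantoms and cohorts generated at test time."""

import numpy as np
import pytest

from istg.phantom import CohortSpec, make_cohort, make_phantom


@pytest.fixture(scope="session")
def phantom32():
    """A 32^3 stage phantom (2 mm voxels) for registration unit tests."""
    return make_phantom(grid=(32, 32, 32), stage_fa=0.5)


@pytest.fixture(scope="session")
def phantom48():
    """The default-size 48^3 stage phantom."""
    return make_phantom()


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 6-scan, 2-group cohort on a 20^3 grid for pipeline unit tests."""
    spec = CohortSpec(
        n_scans=6, n_groups=2, grid=(20, 20, 20), stage_fa=(0.4, 0.6),
        stage_scale=(0.95, 1.05), rigid_rot_deg=3.0, rigid_trans_mm=2.0,
        warp_amplitude=1.5, warp_smoothness=10.0, noise_sd=0.05, seed=7,
    )
    scans, gt, ages = make_cohort(spec)
    return spec, scans, gt, ages


def random_spd_field(shape, rng, scale=1e-3):
    """Random symmetric positive-definite tensor field (6 components)."""
    A = rng.standard_normal(shape + (3, 3))
    M = A @ np.swapaxes(A, -1, -2) * scale / 3.0 + np.eye(3) * scale * 0.1
    from istg.volumes import matrices_to_tensors

    return matrices_to_tensors(M)
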