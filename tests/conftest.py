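import numpy as np
import pytest

from tbm3d import PhantomSpec, SolverParams, TissueImage, normalize_mass
from tbm3d._fields import identity_grid
from tbm3d.phantom import generate_cohort
from tbm3d.transport import solve_transport


def gaussian_image(shape, center, sigma, epsilon=1e-6):
    """Strictly positive unit-mass Gaussian blob."""
    g = identity_grid(shape)
    r2 = sum((g[..., a] - center[a]) ** 2 for a in range(3))
    return normalize_mass(TissueImage(np.exp(-r2 / (2.0 * sigma**2))), epsilon)


@pytest.fixture(scope="session")
def blob_pair_32():
    """Compact blob and its copy translated by an integer vector, 32^3."""
    delta = np.array([3.0, 2.0, -2.0])
    I0 = gaussian_image((32,) * 3, (14.5, 14.5, 15.5), 3.0)
    Ii = gaussian_image((32,) * 3, (17.5, 16.5, 13.5), 3.0)
    return I0, Ii, delta


@pytest.fixture(scope="session")
def small_cohort():
    """Phantom cohort at 32^3 with planted age effect and moderate noise."""
    spec = PhantomSpec(
        n_subjects=16,
        grid_shape=(32, 32, 32),
        effect_amplitude=1.0,
        noise_amplitude=0.5,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_maps(small_cohort):
    params = SolverParams(mp_tolerance=3e-2)
    return [
        solve_transport(small_cohort.template, img, params)
        for img in small_cohort.images
    ]
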