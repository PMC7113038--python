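import numpy as np
import pytest

from radpdl1 import CohortConfig, PhantomSpec, VolumeWithMask, extract_cohort_features, generate_phantom
from radpdl1.features import discretize


def random_discretized(seed: int, shape=(5, 5, 5), G: int = 4):
    """A random small discretized VOI with a random (non-empty) mask."""
    rng = np.random.default_rng(seed)
    intens = rng.normal(0.0, 50.0, size=shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[0] = True
    vm = VolumeWithMask(intens, (1, 1, 1), mask)
    if vm.n_voxels < 2:
        mask.flat[:2] = True
        vm = VolumeWithMask(intens, (1, 1, 1), mask)
    return discretize(vm, G)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(), 1, 42)


@pytest.fixture(scope="session")
def sphere_voi():
    """Digital sphere, radius 10 mm at 1 mm isotropic spacing."""
    g = 24
    idx = np.indices((g, g, g))
    c = (g - 1) / 2.0
    mask = np.sqrt(((idx - c) ** 2).sum(axis=0)) <= 10.0
    return VolumeWithMask(np.ones((g, g, g)), (1.0, 1.0, 1.0), mask)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-effect cohort with both readers' feature tables.

    Session-scoped: several test modules reuse it (selection, model API,
    reliability smoke) to keep the suite fast.
    """
    config = CohortConfig(n_subjects=36, seed=1234)
    spec = PhantomSpec(grid_shape=(24, 24, 24), radii_mm=(10.0, 8.5, 7.0))
    table, f1, f2 = extract_cohort_features(config, spec)
    return table, f1, f2
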