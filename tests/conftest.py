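import numpy as np
import pytest

from ahmo.parcellation import run_ahmo
from ahmo.synthetic import SyntheticSpec, make_toy_atlas, simulate_cohort

# min_size for the 12x12x6 toy grid (the acquisition-resolution default of 50
# voxels is meant for full-size brains; smallest planted subregion here is 24)
TOY_MIN_SIZE = 10


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort: spec, atlas, planted truth, subject volumes."""
    spec = SyntheticSpec(seed=1)
    atlas, truth = make_toy_atlas(spec)
    cohort = simulate_cohort(spec, truth)
    return spec, atlas, truth, cohort


@pytest.fixture(scope="session")
def default_ahmo(default_cohort):
    """AHMO parcellation of the default cohort."""
    _, atlas, _, cohort = default_cohort
    return run_ahmo(cohort, atlas, min_size=TOY_MIN_SIZE, seed=7)


@pytest.fixture(scope="session")
def low_noise_run():
    """Low-noise cohort plus its AHMO result (for exact-recovery checks)."""
    spec = SyntheticSpec(seed=1, noise_sd=0.05)
    atlas, truth = make_toy_atlas(spec)
    cohort = simulate_cohort(spec, truth)
    result = run_ahmo(cohort, atlas, min_size=TOY_MIN_SIZE, seed=7)
    return spec, atlas, truth, cohort, result


def random_weighted_graph(rng, n, density=0.5):
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    A = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = np.triu(A, 1)
    return W + W.T
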