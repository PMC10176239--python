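import dataclasses

import numpy as np
import pytest

from dtialps.synthdata import CohortSpec, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def fast_spec():
    """Small, noise-free phantom spec that keeps tensor fits sub-second."""
    return PhantomSpec(
        grid_shape=(32, 32, 16), n_dirs_per_shell=24, n_b0=3, noise_sigma=0.0
    )


@pytest.fixture(scope="session")
def fast_phantom(fast_spec):
    """Noise-free phantom with perivascular boost 0.3e-3 (analytic ALPS 1.75)."""
    spec = dataclasses.replace(fast_spec, d_perivascular=0.3e-3)
    dwi, truth, layout = generate_phantom(spec)
    return spec, dwi, truth, layout


@pytest.fixture(scope="session")
def cohort_spec():
    return CohortSpec(seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_spd_tensor(rng, scale=1e-3):
    """Random symmetric positive-definite diffusion-scale tensor."""
    A = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(A)
    evals = rng.uniform(0.1, 3.0, 3) * scale
    return q @ np.diag(evals) @ q.T
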