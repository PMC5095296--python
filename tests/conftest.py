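import numpy as np
import pytest

from orthospace.generator import GeneratorParams, make_scenario, simulate_latents, simulate_response
from orthospace.population import (
    MOVEMENT_EPOCH,
    PREPARATORY_EPOCH,
    extract_epoch,
    preprocess,
)


@pytest.fixture(scope="session")
def gen_params():
    return GeneratorParams(seed=11)


@pytest.fixture(scope="session")
def gen_latents(gen_params):
    return simulate_latents(gen_params)


@pytest.fixture(scope="session")
def gen_response(gen_params):
    return simulate_response(gen_params)


@pytest.fixture(scope="session")
def gen_preprocessed(gen_response):
    return preprocess(gen_response)


@pytest.fixture(scope="session")
def gen_epochs(gen_preprocessed):
    return (
        extract_epoch(gen_preprocessed, PREPARATORY_EPOCH),
        extract_epoch(gen_preprocessed, MOVEMENT_EPOCH),
    )


@pytest.fixture(scope="session")
def scenario_fixture():
    """(response, truth) for each of the three planted population structures."""
    out = {}
    for kind in ("orthogonal_linked", "overlapping", "independent"):
        out[kind] = make_scenario(kind, GeneratorParams(seed=23))
    return out


def random_psd(n, rank=None, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    r = rank or n
    a = rng.standard_normal((n, r))
    return scale * a @ a.T / r
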