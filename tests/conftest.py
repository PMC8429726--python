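import numpy as np
import pytest

from chemosched import (
    ObjectiveConfig,
    default_config,
    load_tissue,
    nominal_patient,
)


@pytest.fixture(scope="session")
def bm_params():
    return load_tissue("bone_marrow")


@pytest.fixture(scope="session")
def breast_params():
    return load_tissue("breast")


@pytest.fixture(scope="session")
def ovarian_params():
    return load_tissue("ovarian")


@pytest.fixture(scope="session")
def cfg() -> ObjectiveConfig:
    return default_config()


@pytest.fixture(scope="session")
def nominal():
    return nominal_patient()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_perturbed(bm_params, rng, k=0.2):
    """A random bone-marrow patient with rates scaled within [1-k, 1+k]."""
    f = rng.uniform(1 - k, 1 + k, size=4)
    return bm_params.__class__(
        gamma=bm_params.gamma * f[0],
        delta=0.0,
        alpha=bm_params.alpha * f[1],
        beta=bm_params.beta * f[2],
        lam=bm_params.lam * f[3],
        s=bm_params.s,
    )
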