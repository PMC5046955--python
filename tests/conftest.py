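import numpy as np
import pytest

from cerebdea import HammersteinPlant, SchemeConfig


@pytest.fixture()
def default_plant():
    return HammersteinPlant(rng_seed=0)


@pytest.fixture()
def quiet_plant():
    """Deterministic plant: no sensor noise, no creep."""
    from cerebdea import CreepProcess

    return HammersteinPlant(creep=CreepProcess(kappa_max=0.0),
                            noise_sd=0.0, rng_seed=0)


@pytest.fixture()
def short_cfg():
    """A short scheme-one run for loop-level tests."""
    return SchemeConfig.preset("1", seed=0, duration=60.0,
                               pretrain_duration=30.0)


def rng(seed=0):
    return np.random.default_rng(seed)
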