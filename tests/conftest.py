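import numpy as np
import pytest

from ca3mod.inference import fit_mh
from ca3mod.patterns import CoxParams, sample_cox_train
from ca3mod.stp import ModelSpec
from ca3mod.synth import condition_spec, generate_dataset


@pytest.fixture(scope="session")
def protocol():
    """One naturalistic 100-stimulus protocol shared across the suite."""
    return sample_cox_train(CoxParams(seed=7))


@pytest.fixture(scope="session")
def epsc_dataset(protocol):
    return generate_dataset(condition_spec("excitatory", "control"),
                            protocol, seed=11)


@pytest.fixture(scope="session")
def ipsc_dataset(protocol):
    return generate_dataset(condition_spec("inhibitory", "control"),
                            protocol, seed=13)


@pytest.fixture(scope="session")
def f2_fit(protocol, epsc_dataset):
    """A moderately long excitatory-model fit reused by several tests."""
    return fit_mh(ModelSpec.preset("f2"), protocol, epsc_dataset.trains[0],
                  n_steps=20_000, n_burn=5_000, seed=3)
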