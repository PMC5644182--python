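import dataclasses

import numpy as np
import pytest

import fermprof as fp


@pytest.fixture(scope="session")
def noise_free_config():
    """Default study conditions with every noise source off."""
    return fp.SimulationConfig(
        offgas_cv=0.0, dw_sd=0.0, glucose_sd=0.0, replicate_cv=0.0, seed=11
    )


@pytest.fixture(scope="session")
def scenario_detection():
    return fp.SCENARIO_SEGMENTATION


@pytest.fixture(scope="session")
def noise_free_run(noise_free_config, scenario_detection):
    return fp.simulate_run(noise_free_config, 0, detection=scenario_detection)


@pytest.fixture(scope="session")
def library():
    return fp.demo_library()


def make_config(**kwargs):
    base = dict(offgas_cv=0.0, dw_sd=0.0, glucose_sd=0.0, replicate_cv=0.0, seed=11)
    base.update(kwargs)
    return fp.SimulationConfig(**base)


@pytest.fixture(scope="session")
def make_noise_free_config():
    return make_config


def with_noise(config, **kwargs):
    defaults = fp.SimulationConfig()
    base = dict(
        offgas_cv=defaults.offgas_cv,
        dw_sd=defaults.dw_sd,
        glucose_sd=defaults.glucose_sd,
        replicate_cv=defaults.replicate_cv,
    )
    base.update(kwargs)
    return dataclasses.replace(config, **base)
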