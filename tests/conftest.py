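import numpy as np
import pytest

from emgresp.pipeline import dataset_from_cohort
from emgresp.preprocessing import PrepConfig
from emgresp.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def effect_cfg() -> SimConfig:
    """Strong planted effect (60 Hz spectral shift), sized for fast tests."""
    return SimConfig(
        n_participants=10,
        muscles_min=4,
        muscles_max=6,
        fs=2000.0,
        mvc_duration=3.0,
        rest_duration=2.0,
        effect_medf_shift=60.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def effect_cohort(effect_cfg):
    return generate_cohort(effect_cfg)


@pytest.fixture(scope="session")
def effect_dataset(effect_cohort):
    """Trial dataset + tau label table for the strong-effect cohort."""
    return dataset_from_cohort(effect_cohort, prep_cfg=PrepConfig(window_s=2.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
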