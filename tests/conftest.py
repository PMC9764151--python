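import pytest

from hkecg.generic_training import TrainConfig
from hkecg.pipeline import generate_and_preprocess, train_generic_on_cohort
from hkecg.resnet1d import resnet18_1d
from hkecg.synthetic_cohort import separable_config


@pytest.fixture(scope="session")
def desk_spec():
    """Narrow resnet18_1d used throughout the desk-scale runs."""
    return resnet18_1d(width_scale=0.25)


@pytest.fixture(scope="session")
def desk_train_config():
    """Desk-scale training override of the study protocol (see methods)."""
    return TrainConfig(learning_rate=1e-3, batch_size=32, max_epochs=5, seed=0)


@pytest.fixture(scope="session")
def separable_pre():
    """Noise-free, homogeneous cohort preprocessed down to beats."""
    _, pre = generate_and_preprocess(separable_config(), run_qc=False)
    return pre


@pytest.fixture(scope="session")
def pretrained_small(separable_pre, desk_spec, desk_train_config):
    checkpoint, summary = train_generic_on_cohort(separable_pre, desk_spec,
                                                  desk_train_config)
    return checkpoint, summary
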