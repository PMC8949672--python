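import numpy as np
import pytest

from arrhythmianet.classify import ClassifierSpec
from arrhythmianet.cwt import WaveletConfig
from arrhythmianet.net import NetConfig, TrainConfig
from arrhythmianet.pipeline import PipelineConfig
from arrhythmianet.synth import well_separated_suite


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_pipeline_config():
    """Small, fast geometry used by the pipeline-level tests."""
    return PipelineConfig(
        seed=7,
        wavelet=WaveletConfig(output_side=16),
        net=NetConfig(input_side=16, conv_channels=(2, 3, 4), n_classes=2),
        train=TrainConfig(epochs=2, batch_size=8, seed=7),
        cof_k=3,
        classifier=ClassifierSpec(kind="svm", kernel="linear"),
    )


@pytest.fixture
def tiny_dataset():
    return well_separated_suite(2, 10, seed=7)
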