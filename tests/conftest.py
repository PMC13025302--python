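import numpy as np
import pytest

from icseg import ModelConfig, SegmentationModel, SyntheticTaskConfig
from icseg.synthetic import generate_task_dataset


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def tiny_model(tiny_config) -> SegmentationModel:
    return SegmentationModel(tiny_config, seed=123)


@pytest.fixture(scope="session")
def tiny_synth_config() -> SyntheticTaskConfig:
    # 32px scenes to match the tiny model; few samples for speed
    return SyntheticTaskConfig(image_size=32, samples_per_class=8, eval_samples=4, seed=42)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_synth_config):
    return generate_task_dataset(tiny_synth_config, "train")


@pytest.fixture(scope="session")
def tiny_eval_dataset(tiny_synth_config):
    return generate_task_dataset(tiny_synth_config, "eval")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
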