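import pytest

from digibone.gp_scale import default_scale
from digibone.segmentation import SegTrainConfig, train_segmenter
from digibone.synthdata import SamplerConfig, sample_phantoms


@pytest.fixture(scope="session")
def male_scale():
    return default_scale("male")


@pytest.fixture(scope="session")
def female_scale():
    return default_scale("female")


@pytest.fixture(scope="session")
def phantom_sampler():
    return SamplerConfig(image_size=128)


@pytest.fixture(scope="session")
def segmenter_200(male_scale, phantom_sampler):
    """Segmenter trained on 200 phantoms; shared by the heavier tests."""
    train = sample_phantoms(200, phantom_sampler, male_scale, 11)
    return train_segmenter(train, SegTrainConfig(epochs=6, seed=0))


@pytest.fixture(scope="session")
def heldout_50(male_scale, phantom_sampler):
    return sample_phantoms(50, phantom_sampler, male_scale, 12)
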