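import numpy as np
import pytest

from stimfuzz.constraints import (
    CORTICAL_LIMITS,
    RETINAL_LIMITS,
    ElectrodeArraySpec,
    StimulationVector,
)
from stimfuzz.mutation import ImageInput, SeedSet
from stimfuzz.testbed import (
    MLPEncoder,
    ToyCorticalEncoder,
    ToyRetinalEncoder,
    default_seed_images,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_array():
    return ElectrodeArraySpec(n_electrodes=4, layout_label="2x2 toy")


@pytest.fixture(scope="session")
def retinal_encoder():
    return ToyRetinalEncoder()


@pytest.fixture(scope="session")
def cortical_encoder():
    return ToyCorticalEncoder()


@pytest.fixture(scope="session")
def mlp_encoder():
    return MLPEncoder(image_shape=(12, 12), hidden=16, weight_seed=7)


@pytest.fixture
def retinal_seeds():
    seeds = SeedSet()
    for img in default_seed_images(30, 30):
        seeds.add_image(img)
    return seeds


def random_stim(rng, spec, f_hi=300.0, p_hi=20.0, a_hi=200.0):
    """Random valid stimulation vector for property tests."""
    n = spec.n_electrodes
    return StimulationVector(
        frequency=rng.uniform(0.0, f_hi, n),
        pulse_duration=rng.uniform(0.0, p_hi, n),
        amplitude=rng.uniform(0.0, a_hi, n) * (rng.random(n) > 0.2),
        array_spec=spec,
    )


def mid_gray(h=30, w=30, value=0.5, input_id="gray"):
    return ImageInput(pixels=np.full((h, w), value), input_id=input_id)
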