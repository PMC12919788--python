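import numpy as np
import pytest
from hypothesis import settings

from piwislice import ModelConfig, build_model
from piwislice.simulate import generate_benchmark

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_config() -> ModelConfig:
    return ModelConfig(L=6, d=4, d_ins=2, conv_filters=4, kernel=3, n_layers=1, n_heads=2)


@pytest.fixture
def tiny_benchmark():
    """Two guides of length 6 with a small noisy library."""
    data, rule = generate_benchmark(n_guides=2, seed=11, L=6, noise_sd=0.1)
    return data, rule


@pytest.fixture
def bench4():
    """Four guides, full-length default library (the standard benchmark shape)."""
    data, rule = generate_benchmark(n_guides=4, seed=5)
    return data, rule


def zeroed(model):
    """Set every parameter of a model to zero, in place."""
    for p in model.parameters():
        p.data[...] = 0.0
    return model
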