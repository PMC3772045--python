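import numpy as np
import pytest

from shcspeech.dynamics import (
    GenerativeModel,
    SimulationConfig,
    attractor_input,
    default_model,
    simulate_hierarchy,
)
from shcspeech.inference import InferenceSettings
from shcspeech.synth import make_class_specs, make_word


FAST = InferenceSettings(n_inner=2)


def model_from_profiles(seed: int) -> GenerativeModel:
    """A generative model whose feedback columns encode 8 random spectral
    targets (the shape of a learned word template)."""
    rng = np.random.default_rng(seed)
    profiles = rng.uniform(0.1, 0.9, size=(8, 6))
    m = default_model()
    m.fb.I = np.stack([attractor_input(p, m.hop) for p in profiles], axis=1)
    return m


@pytest.fixture(scope="session")
def word_specs():
    return make_class_specs(10, seed=0)


@pytest.fixture(scope="session")
def self_generated():
    """A known model and the noise-free stimulus it generates."""
    m = model_from_profiles(0)
    z, latents = simulate_hierarchy(m, SimulationConfig(T=100, seed=0))
    return m, z, latents


@pytest.fixture(scope="session")
def trained_module(word_specs):
    from shcspeech.agent import train_module

    z = make_word(word_specs[0], token_seed=1)
    mod = train_module(word_specs[0].label, [z], settings=InferenceSettings(n_inner=4))
    return mod, z
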