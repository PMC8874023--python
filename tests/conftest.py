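"""Shared fixtures: generator config, seeded recordings, a trained denoiser.

The trained denoiser and the ten-recording evaluation battery are expensive,
so they are session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import blinkclean as bc
from blinkclean.config import GeneratorConfig, ICAConfig, TrainConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

TRAIN_SEED = 20220211
HELD_OUT_SEED = 1


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def recording_pair(gen_config):
    """Seeded 60-s clean/contaminated recording pair plus blink train."""
    return bc.generate_recording(60, gen_config, HELD_OUT_SEED)


@pytest.fixture(scope="session")
def desk_dataset(gen_config):
    """Desk-scale training set: 10,000 paired windows, fixed seed."""
    return bc.generate_dataset(10_000, gen_config, TRAIN_SEED)


@pytest.fixture(scope="session")
def trained_denoiser(desk_dataset):
    """Denoiser trained on the desk-scale set with the default schedule
    (10 epochs, batch 128, seed 20220211)."""
    model = bc.build_model(seed=TRAIN_SEED)
    return bc.train(model, desk_dataset, TrainConfig(seed=TRAIN_SEED))


@pytest.fixture(scope="session")
def trained_denoiser_headline(desk_dataset):
    """The abbreviated 5-epoch run used by the scaled-down headline check."""
    model = bc.build_model(seed=TRAIN_SEED)
    return bc.train(model, desk_dataset, TrainConfig(epochs=5, seed=TRAIN_SEED))


@pytest.fixture(scope="session")
def method_battery(gen_config, trained_denoiser):
    """Ten seeded test recordings cleaned by CNN, ICA and regression.

    Returns a list of dicts with the recordings and the per-method metric
    tables, used by the cross-method ordering and amplitude checks.
    """
    out = []
    for seed in range(101, 111):
        clean, cont, _ = bc.generate_recording(60, gen_config, seed)
        cleaned = {
            "cnn": bc.clean_recording(trained_denoiser, cont),
            "ica": bc.ica_clean(cont, ICAConfig(seed=seed))[0],
            "reg": bc.regression_clean(cont).cleaned,
        }
        report = bc.compare_methods(clean, cont, cleaned)
        out.append({"clean": clean, "contaminated": cont,
                    "cleaned": cleaned, "report": report, "seed": seed})
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
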