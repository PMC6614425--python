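import numpy as np
import pytest
from hypothesis import settings

from memcolor import hue_model, pipeline, synthetic_data

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return synthetic_data.make_stimulus_catalog()


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (catalog, measured, matches, config)."""
    cfg = synthetic_data.SimulationConfig(seed=11)
    rng = np.random.default_rng(cfg.seed)
    catalog, measured, matches = synthetic_data.generate_study(cfg, rng)
    return cfg, catalog, measured, matches


@pytest.fixture(scope="session")
def reference(study):
    cfg, _, measured, _ = study
    return synthetic_data.reference_lab(measured, cfg.monitor_white, cfg.scene_white)


@pytest.fixture(scope="session")
def fitted(study, reference):
    cfg, catalog, _, matches = study
    fits = pipeline.fit_models(matches, catalog, reference)
    residuals = hue_model.hue_residuals(matches, fits, reference)
    return fits, residuals


def noise_free_config(**overrides) -> synthetic_data.SimulationConfig:
    """A generator config with every random effect and noise source off."""
    base = dict(
        seed=0,
        lightness_hue_slope=0.0,
        lps_chroma_compression=1.0,
        delta_face=0.0,
        photo_fraction=0.0,
        race_lightness_shift=0.0,
        participant_sd=0.0,
        match_noise_sd=0.0,
        lightness_noise_sd=0.0,
        lips_variance_inflation=1.0,
    )
    base.update(overrides)
    return synthetic_data.SimulationConfig(**base)
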