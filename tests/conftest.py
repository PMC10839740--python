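"""Shared fixtures: synthetic cohorts and fitted models at two scales.

``small_*`` fixtures are desk-scale (few ROIs, few sites) for fast unit
tests; ``default_*`` fixtures use the generator's default study conditions
and are session-scoped because the reference fit is the expensive step.
"""

import warnings

import numpy as np
import pytest

from hbrnorm import hbr, transfer
from hbrnorm.synthetic import (
    GeneratorConfig,
    WaveSpec,
    generate_reference,
    generate_target,
)


def small_generator_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_rois=4,
        roi_names=["a", "b", "c", "d"],
        roi_area=np.array([30.0, 60.0, 120.0, 240.0]),
        n_sites_ref=8,
        subjects_per_site_ref=60,
        mu_alpha=np.array([2.3, 2.45, 2.6, 2.75]),
        mu_beta=np.array([-0.014, -0.011, -0.009, -0.007]),
        sex_offset=np.full(4, 0.03),
        sigma0=np.full(4, 0.12),
        delta=np.array([0.25, -0.25, 0.0, 0.0]),
        target_waves=[
            WaveSpec("wave1", "scannerA", (6.0, 10.0), 150),
            WaveSpec("wave2", "scannerB", (9.0, 12.0), 150),
            WaveSpec("wave3", "scannerB", (13.0, 17.0), 150),
        ],
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return small_generator_config()


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config, seed=11)


@pytest.fixture(scope="session")
def small_target(small_config):
    return generate_target(small_config, seed=12)


@pytest.fixture(scope="session")
def small_model(small_config, small_reference):
    cohort, _ = small_reference
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return hbr.fit_rois(cohort, small_config.roi_names,
                            sampler_config=hbr.SamplerConfig(seed=13))


@pytest.fixture(scope="session")
def small_adapted(small_model, small_target):
    cohort, _ = small_target
    aset, remainder = transfer.sample_adaptation_set(cohort, 40, seed=14)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = transfer.adapt(
            small_model, aset,
            sampler_config=hbr.SamplerConfig(seed=15, draws=500, warmup=500))
    return model, aset, remainder


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_reference(default_config):
    return generate_reference(default_config, seed=1)


@pytest.fixture(scope="session")
def default_reference_model(default_config, default_reference):
    cohort, _ = default_reference
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return hbr.fit_rois(cohort, default_config.roi_names,
                            sampler_config=hbr.SamplerConfig(seed=3))
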