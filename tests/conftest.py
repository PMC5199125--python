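import numpy as np
import pytest

from circatree.lineages import GeneratorConfig, generate_movie


@pytest.fixture(scope="session")
def wt_low_movie():
    """One default wild-type low-light movie (120 h, seeded)."""
    return generate_movie(GeneratorConfig.from_preset("WT_LOW", seed=1))


@pytest.fixture(scope="session")
def sigc_ko_movie():
    return generate_movie(GeneratorConfig.from_preset("SIGC_KO_LOW", seed=1))


@pytest.fixture(scope="session")
def clean_wt_movie():
    """Noise-free, non-desynchronising wild-type movie for exact recovery."""
    cfg = GeneratorConfig.from_preset(
        "WT_LOW",
        seed=3,
        meas_noise_cv=0.0,
        phase_diffusion_sd_h_per_cycle=0.0,
    )
    return generate_movie(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
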