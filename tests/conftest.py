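import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# simulated extreme pyramids occasionally clip at 100%; the estimators under
# test log it, which is noise here
logging.getLogger("qtlpyramid.synthetic_data").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def table1_panel():
    from qtlpyramid import datasets

    return datasets.load_table1_panel()


@pytest.fixture(scope="session")
def full_panel():
    """Study panel plus one reconstructed single-QTL line per locus."""
    from qtlpyramid.synthetic_data import generate_panel

    return generate_panel("paper_preset_full")


@pytest.fixture(scope="session")
def noise_free_records(full_panel):
    """Deterministic phenotypes: reconstructed additive effects, programmed
    diminishing epistasis, zero noise."""
    from qtlpyramid.synthetic_data import (
        diminishing_epistasis,
        generate_phenotypes,
        paper_like_config,
    )

    cfg = paper_like_config(epistasis=diminishing_epistasis(3.5), noise_sd=0.0)
    return generate_phenotypes(full_panel, cfg), cfg
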