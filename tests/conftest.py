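import logging

import pytest

from proteoscreen.preprocess import preprocess
from proteoscreen.simulate import SimConfig, generate_study

logging.getLogger("proteoscreen").setLevel(logging.WARNING)


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A scaled-down study: fast to generate, same structure as the default."""
    base = dict(
        n_cases_discovery=60,
        n_cases_validation=30,
        n_controls=10,
        n_proteins=80,
        n_de_proteins=30,
        n_effect_proteins=6,
        de_shift=1.2,
        missing_rate=0.05,
        rng_seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def small_processed(small_study):
    dmat, _ = preprocess(small_study.discovery_matrix)
    vmat, _ = preprocess(small_study.validation_matrix)
    return dmat, vmat
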