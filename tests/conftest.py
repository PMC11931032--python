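"""Shared fixtures.

The two GAN training runs are session-scoped because they are by far
the most expensive fixtures; every test that needs a trained model
shares the same run.
"""
import numpy as np
import pytest

from catdeblur import experiments

SEED = 11


@pytest.fixture(scope="session")
def smoke_corpora():
    return experiments.build_smoke_corpora(SEED)


@pytest.fixture(scope="session")
def deblur_smoke():
    return experiments.run_deblur_smoke(SEED)


@pytest.fixture(scope="session")
def translator_smoke(deblur_smoke):
    return experiments.run_translator_smoke(
        SEED, deblur_generator=deblur_smoke["generator"])


@pytest.fixture(scope="session")
def end_to_end(deblur_smoke, translator_smoke):
    return experiments.run_end_to_end(deblur_smoke["generator"],
                                      translator_smoke["generator"],
                                      deblur_smoke["held"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
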