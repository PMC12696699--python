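"""Shared fixtures: synthetic datasets at two scales.

``synth_default`` is the full study-condition fixture (5 modules x 60
genes + 100 background, 200 samples, seed 7); ``synth_small`` is a scaled
-down instance for fast unit tests of the same machinery.
"""

import numpy as np
import pytest

import modgrn as mg


@pytest.fixture(scope="session")
def synth_default():
    return mg.generate(mg.SynthConfig(seed=7))


@pytest.fixture(scope="session")
def synth_default_logX(synth_default):
    return mg.log_transform(synth_default.expression)


@pytest.fixture(scope="session")
def synth_small():
    cfg = mg.SynthConfig(
        seed=11,
        n_modules=3,
        genes_per_module=20,
        n_background_genes=15,
        n_samples=80,
        edges_per_module=15,
    )
    return mg.generate(cfg)


@pytest.fixture(scope="session")
def synth_small_logX(synth_small):
    return mg.log_transform(synth_small.expression)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
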