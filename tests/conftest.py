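import numpy as np
import pytest

import psspkit as pk


@pytest.fixture(scope="session")
def small_corpus():
    """20 realistic-emission sequences with ss8 + RSA tracks, plus tallies."""
    cfg = pk.GeneratorConfig(n_sequences=20, min_length=20, max_length=35,
                             seed=5)
    records, tallies = pk.generate_corpus(cfg)
    return cfg, records, tallies


@pytest.fixture(scope="session")
def deterministic_corpus():
    """Sequences whose residues are a function of the SS category."""
    cfg = pk.GeneratorConfig(n_sequences=40, min_length=25, max_length=40,
                             emissions=pk.deterministic_emissions(), seed=9)
    records, tallies = pk.generate_corpus(cfg)
    return cfg, records, tallies


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
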