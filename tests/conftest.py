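import numpy as np
import pytest

from plauscomp.synthetic import CorpusConfig, generate_corpus


@pytest.fixture(scope="session")
def default_synthetic():
    """The default synthetic corpus and its ground-truth ledger (shared:
    generation takes a few seconds)."""
    return generate_corpus(CorpusConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
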