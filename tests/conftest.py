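import random

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def strategy():
    from radex import packaged_strategy
    return packaged_strategy()


@pytest.fixture(scope="session")
def lexicon():
    from radex import default_lexicon
    return default_lexicon()


@pytest.fixture
def rng():
    return random.Random(20240917)
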