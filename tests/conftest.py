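import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from skinmdt.corpus import GenerationConfig, generate_corpus
from skinmdt.evaluation import load_published_matrix
from skinmdt.fixtures import load_structured_cases


@pytest.fixture(scope="session")
def published_matrix():
    return load_published_matrix()


@pytest.fixture(scope="session")
def structured_cases():
    return load_structured_cases()


@pytest.fixture(scope="session")
def clean_corpus():
    """Noise-free 120-patient corpus shared across extraction tests."""
    return generate_corpus(GenerationConfig(n_patients=120, seed=20240301))


@pytest.fixture(scope="session")
def noisy_corpus():
    """Corpus with heavy lexical noise (hedging, respellings, distractors)."""
    return generate_corpus(
        GenerationConfig(n_patients=120, seed=20240302, noise_level=0.6)
    )
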