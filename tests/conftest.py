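import warnings

import numpy as np
import pytest

from cpvs import (LibrarySpec, exhaustive_screen, generate_library,
                  make_surrogate_oracle)
from cpvs.signatures import build_vocabulary, signature_matrix

BENCH_LIBRARY_SEED = 42
BENCH_ORACLE_SEED = 7
BENCH_SIZE = 20_000


@pytest.fixture(scope="session")
def small_library():
    """3 000 random molecules shared by unit tests."""
    return generate_library(LibrarySpec(n_molecules=3000, seed=BENCH_LIBRARY_SEED))


@pytest.fixture(scope="session")
def bench_library():
    """The 20 000-molecule screening benchmark library."""
    return generate_library(
        LibrarySpec(n_molecules=BENCH_SIZE, seed=BENCH_LIBRARY_SEED))


@pytest.fixture(scope="session")
def bench_features(bench_library):
    vocab = build_vocabulary(bench_library).freeze()
    X = signature_matrix(bench_library, vocab)
    return vocab, X


@pytest.fixture(scope="session")
def bench_oracle(bench_library, bench_features):
    return make_surrogate_oracle(bench_library, seed=BENCH_ORACLE_SEED,
                                 features=bench_features)


@pytest.fixture(scope="session")
def bench_exhaustive(bench_library, bench_oracle):
    return exhaustive_screen(bench_library, bench_oracle)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet():
    """Silence expected warnings (annotation drops, early stops...)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
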