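import numpy as np
import pytest

from afpid.alphabets import builtin_alphabets
from afpid.features import SchemeSpec, build_scheme_matrix
from afpid.synthetic import BenchmarkSpec, generate_benchmark


@pytest.fixture(scope="session")
def registry():
    return builtin_alphabets()


@pytest.fixture(scope="session")
def small_benchmark():
    """80+80 planted-motif benchmark shared by classifier/GA/voting tests."""
    return generate_benchmark(BenchmarkSpec(n_pos=80, n_neg=80, seed=7))


@pytest.fixture(scope="session")
def d0_matrix(small_benchmark, registry):
    return build_scheme_matrix(
        small_benchmark.dataset.records, SchemeSpec("gapped_dipeptide", g=0), registry
    )


@pytest.fixture(scope="session")
def d2_matrix(small_benchmark, registry):
    return build_scheme_matrix(
        small_benchmark.dataset.records, SchemeSpec("gapped_dipeptide", g=2), registry
    )


@pytest.fixture(scope="session")
def small_labels(small_benchmark):
    return [r.label for r in small_benchmark.dataset.records]


@pytest.fixture(scope="session")
def small_signs(small_labels):
    return np.array([1 if lab == "AFP" else -1 for lab in small_labels])
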