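import numpy as np
import pytest

from karyosig.spectrum import N_TYPES, spectrum_from_counts


@pytest.fixture(scope="session")
def universe():
    from karyosig.spectrum import enumerate_types

    return enumerate_types()


def make_spectrum(counts, label="s", n_cases=None):
    """Spectrum from a sparse {index: count} dict or full vector."""
    if isinstance(counts, dict):
        vec = np.zeros(N_TYPES, dtype=np.int64)
        for idx, c in counts.items():
            vec[idx] = c
    else:
        vec = np.asarray(counts, dtype=np.int64)
    total = int(vec.sum())
    return spectrum_from_counts(vec, label=label, n_cases=n_cases or max(total, 1))


@pytest.fixture
def uniform_spectrum():
    return make_spectrum(np.full(N_TYPES, 4), label="uniform")
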