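import numpy as np
import pytest

from texrip import synthetic


@pytest.fixture(scope="session")
def small_truth():
    """A compact synthetic study shared by read-only tests."""
    sequence, truth = synthetic.make_truth(
        genome_length=30_000, n_genes=20, n_tss=10, n_tps=10, n_peaks=6,
        n_asrna=6, seed=42,
    )
    return sequence, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
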