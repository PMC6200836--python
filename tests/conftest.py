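import numpy as np
import pandas as pd
import pytest

from somascape.signatures import load_reference_signatures
from somascape.spectrum import NATIVE_CHANNELS


class DictGenome:
    """Minimal FASTA-accessor stand-in: chrom -> sequence string."""

    def __init__(self, seqs: dict[str, str]):
        self._seqs = seqs

    def __getitem__(self, chrom):
        return self._seqs[chrom]


@pytest.fixture(scope="session")
def reference_native() -> pd.DataFrame:
    return load_reference_signatures(convention="native")


@pytest.fixture(scope="session")
def reference_cosmic() -> pd.DataFrame:
    return load_reference_signatures(convention="cosmic")


def planted_spectrum(reference_native, signatures, alpha, n_samples, n_mutations, seed):
    """Spectrum matrix drawn from a Dirichlet mixture of reference profiles."""
    rng = np.random.default_rng(seed)
    P = reference_native.loc[list(signatures)].to_numpy()
    rows = [rng.multinomial(n_mutations, rng.dirichlet(alpha) @ P)
            for _ in range(n_samples)]
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(n_samples)],
                        columns=NATIVE_CHANNELS)
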