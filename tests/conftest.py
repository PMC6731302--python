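import numpy as np
import pandas as pd
import pytest

from teherit.pipeline import make_noiseless_fixture


def make_variants(positions, chrom="1", maf=0.3):
    """Variant table at explicit 1-based positions."""
    positions = np.asarray(positions)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "a1": "A",
            "a2": "G",
            "maf": maf,
        }
    )


@pytest.fixture(scope="session")
def noiseless():
    """Exact-algebra fixture: chi2_j = N * sum_c l(j,c) tau_c + 1."""
    return make_noiseless_fixture(seed=0)


@pytest.fixture
def variants100():
    return make_variants(1 + 1000 * np.arange(100))
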