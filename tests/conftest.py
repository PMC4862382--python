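import numpy as np
import pandas as pd
import pytest

from pleioscan.sumstats_io import SUMSTATS_COLUMNS, zscore_to_pvalue


def make_sumstats(z, chrom="1", spacing=10_000, snp_prefix="rs", n=1000,
                  a1="A", a2="G"):
    """Canonical summary-statistics frame from a Z vector (SE fixed at 1)."""
    z = np.asarray(z, dtype=float)
    m = z.size
    return pd.DataFrame(
        {
            "SNP": [f"{snp_prefix}{i + 1}" for i in range(m)],
            "CHR": chrom,
            "BP": (np.arange(m) + 1) * spacing,
            "A1": a1,
            "A2": a2,
            "BETA": z,
            "SE": 1.0,
            "Z": z,
            "P": zscore_to_pvalue(z),
            "N": n,
        }
    )[SUMSTATS_COLUMNS]


@pytest.fixture
def sumstats_factory():
    return make_sumstats


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
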