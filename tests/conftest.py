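import numpy as np
import pandas as pd
import pytest

from chromtss import synthetic_data as sd
from chromtss.types import ExpressionMatrix, GenomicInterval, RtssRecord


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic study shared by read-only tests."""
    return sd.generate_dataset(
        n_rtss=300, S=30, n_chroms=2, chrom_length=4_000_000, n_genes=150, seed=7
    )


@pytest.fixture()
def toy_catalog():
    return [
        RtssRecord("a", GenomicInterval("chr1", 1000, 1100, "+")),
        RtssRecord("b", GenomicInterval("chr1", 5000, 5080, "-")),
        RtssRecord("c", GenomicInterval("chr2", 100, 200, "+")),
    ]


@pytest.fixture()
def toy_expression():
    counts = pd.DataFrame(
        {"focal": [10, 0, 2], "s1": [5, 3, 1]},
        index=pd.Index(["a", "b", "c"], name="rtss_id"),
    )
    return ExpressionMatrix(counts)


def random_profiles(rng: np.random.Generator, n: int, bins: int = 48) -> pd.DataFrame:
    return pd.DataFrame(
        rng.random((n, bins)) * 10, index=[f"p{i}" for i in range(n)]
    )
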