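import numpy as np
import pandas as pd
import pytest
from scipy import stats


def convolution_skellam_pmf(k: int, lam1: float, lam2: float, terms: int = 400) -> float:
    """Brute-force Skellam pmf by truncated convolution of two Poisson pmfs.

    P(Y1 - Y2 = k) = sum_j Pois(j + k; lam1) * Pois(j; lam2), truncated far
    into both tails.  Independent of the Bessel-function implementation.
    """
    j = np.arange(0, terms)
    return float(np.sum(stats.poisson.pmf(j + k, lam1) * stats.poisson.pmf(j, lam2)))


@pytest.fixture
def tiny_counts():
    """Hand-written allele-count table covering the filtering edge cases."""
    return pd.DataFrame(
        {
            "subject": ["s1", "s1", "s1", "s2", "s2", "s2"],
            "tissue": ["t1", "t1", "t2", "t1", "t1", "t1"],
            "gene": ["GA", "GA", "GA", "GB", "GB", "GC"],
            "snp": ["rs1", "rs2", "rs1", "rs3", "rs4", "rs5"],
            "region": ["utr3", "exon", "utr3", "intron", "intergenic", "utr5"],
            "ref_count": [6, 3, 10, 50, 50, 2],
            "var_count": [9, 100, 20, 50, 50, 500],
        }
    )
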