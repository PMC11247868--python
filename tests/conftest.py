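import numpy as np
import pandas as pd
import pytest

from totem import MarkerMatrix
from totem.mcb import MCB, BetaMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_beta():
    """4 CpGs at 10/50/90/300; first three perfectly correlated."""
    base = np.array([0.1, 0.4, 0.6, 0.9, 0.2])
    values = np.vstack([
        base,
        base * 0.9 + 0.05,
        base * 0.8 + 0.1,
        np.array([0.9, 0.1, 0.5, 0.2, 0.7]),
    ])
    sites = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [10, 50, 90, 300]})
    return BetaMatrix(sites=sites, values=values,
                      samples=[f"s{i}" for i in range(5)])


def random_beta_matrix(rng, n_sites=30, n_samples=8, block_prob=0.6):
    """Random matrix mixing correlated stretches and independent sites."""
    chrom = "chr1"
    positions = np.cumsum(rng.integers(10, 200, size=n_sites)) + 100
    values = np.empty((n_sites, n_samples))
    i = 0
    while i < n_sites:
        if rng.random() < block_prob:
            run = int(rng.integers(2, 6))
            latent = rng.random(n_samples)
            for k in range(min(run, n_sites - i)):
                values[i] = np.clip(latent + rng.normal(0, 0.01, n_samples), 0, 1)
                i += 1
        else:
            values[i] = rng.random(n_samples)
            i += 1
    sites = pd.DataFrame({"chrom": [chrom] * n_sites, "pos": positions})
    return BetaMatrix(sites=sites, values=values,
                      samples=[f"s{j}" for j in range(n_samples)])


def make_marker_matrix(mfc, n_informative, coverage=None, samples=None, markers=None):
    mfc = np.asarray(mfc)
    n_informative = np.asarray(n_informative)
    if coverage is None:
        coverage = n_informative
    samples = samples or [f"s{i}" for i in range(mfc.shape[0])]
    markers = markers or [f"m{j}" for j in range(mfc.shape[1])]
    return MarkerMatrix(
        mfc=pd.DataFrame(mfc, index=samples, columns=markers),
        n_informative=pd.DataFrame(n_informative, index=samples, columns=markers),
        coverage=pd.DataFrame(np.asarray(coverage), index=samples, columns=markers),
    )
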