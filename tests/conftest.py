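import numpy as np
import pandas as pd
import pytest

from bulkmap.simdata import SimConfig, simulate_study


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale study: small enough for sub-second simulation."""
    return SimConfig(
        n_chromosomes=2,
        chrom_length_bp=400_000,
        n_markers_per_chrom=400,
        qtl_position=("chr1", 200_000),
        n_genes_per_chrom=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture()
def random_track(rng):
    """Random SNP-index track (already oriented) for oracle comparisons."""
    m = 500
    chrom = np.where(np.arange(m) < m // 2, "chr1", "chr2")
    pos = np.concatenate(
        [
            np.sort(rng.choice(np.arange(1, 100_001), m // 2, replace=False)),
            np.sort(rng.choice(np.arange(1, 100_001), m - m // 2, replace=False)),
        ]
    )
    dh = rng.poisson(50, m) + 7
    dl = rng.poisson(50, m) + 7
    ah = rng.binomial(dh, 0.5)
    al = rng.binomial(dl, 0.5)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "dwarf_high": ah,
            "depth_high": dh,
            "dwarf_low": al,
            "depth_low": dl,
            "index_high": ah / dh,
            "index_low": al / dl,
            "delta": ah / dh - al / dl,
        }
    )
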