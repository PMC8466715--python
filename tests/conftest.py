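import numpy as np
import pandas as pd
import pytest

from haplarch.containers import SnpMap
from haplarch.hapmodel import build_cluster_model


def make_snp_map(n_snps, spacing_cm=0.05, chrom="1", start_cm=0.0):
    rows = [
        (chrom, f"snp{i}", int(i * spacing_cm * 1e6) + 1, start_cm + i * spacing_cm)
        for i in range(n_snps)
    ]
    return SnpMap(pd.DataFrame(rows, columns=["chrom", "snp_id", "bp", "cm"]))


@pytest.fixture
def snp_map_160():
    return make_snp_map(160)


@pytest.fixture
def chain_model():
    """Single-chain model with allele-1 frequency 0.5 at both SNPs, no floor.

    Built from equal counts of 00/01/10/11, whose level-1 nodes merge
    (identical continuations), leaving one node per level.
    """
    haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 3, dtype=np.int8)
    return build_cluster_model(haps, merge_tolerance=0.15, edge_floor=0.0)


@pytest.fixture
def split_model():
    """Model from {00 x9, 11 x9}: two distinct level-1 nodes (TV distance 1)."""
    haps = np.array([[0, 0]] * 9 + [[1, 1]] * 9, dtype=np.int8)
    return build_cluster_model(haps, merge_tolerance=0.15)


def random_model(rng, n_hap=None, n_snps=None, tolerance=None):
    n_hap = n_hap or int(rng.integers(4, 20))
    n_snps = n_snps or int(rng.integers(2, 5))
    tolerance = tolerance if tolerance is not None else float(rng.uniform(0, 0.3))
    haps = rng.integers(0, 2, (n_hap, n_snps)).astype(np.int8)
    return build_cluster_model(haps, merge_tolerance=tolerance)


def random_genotype(rng, n_snps, missing_rate=0.2):
    g = rng.integers(0, 3, n_snps).astype(np.int8)
    g[rng.random(n_snps) < missing_rate] = -1
    return g
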