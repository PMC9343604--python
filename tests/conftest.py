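"""Shared fixtures: tiny hand-built matrices and one full neutral scan."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sweepscan as ss
from sweepscan import pipeline
from sweepscan.hapio import HaplotypeMatrix


def make_variants(positions, chrom="chr1", polarizable=True):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": np.asarray(positions, dtype=np.int64),
            "variant_id": [f"{chrom}:{p}" for p in positions],
            "ancestral_allele": "A",
            "derived_allele": "G",
            "polarizable": polarizable,
        }
    )


def make_hap(matrix, positions=None, chrom="chr1", label="pop"):
    matrix = np.asarray(matrix, dtype=np.int8)
    if positions is None:
        positions = 1000 * (1 + np.arange(matrix.shape[1]))
    sample_ids = [f"s{i}" for i in range(matrix.shape[0] // 2)]
    return HaplotypeMatrix(label, matrix, sample_ids, make_variants(positions, chrom))


@pytest.fixture(scope="session")
def neutral_dataset():
    """Default-sized neutral dataset (200 genes, 2 x 5,000 SNPs, 3 pops)."""
    return ss.simulate_dataset(ss.neutral_config(1))


@pytest.fixture(scope="session")
def neutral_scan(neutral_dataset):
    """Full scan of the neutral dataset with one reference configuration."""
    ds = neutral_dataset
    return pipeline.run_scan(
        ds.haps,
        ds.genes,
        ds.gmap,
        "target",
        [ss.Comparison("sa", "ref_sa", "ref_global")],
        ss.ScanParams(k_pool=50),
    )
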