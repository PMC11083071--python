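from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from recland.core import FineScaleMap
from recland.io_formats import VariantTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_map() -> FineScaleMap:
    """Six SNPs; one obvious hotspot run and one coldspot run.

    Weighted mean rate = 109.8 / 10000 = 0.01098, so the 10x threshold is
    0.1098 and the 0.1x threshold is 0.001098.
    """
    return FineScaleMap(
        chrom="1",
        positions=np.array([0, 1000, 1100, 1200, 2200, 10000]),
        rates=np.array([0.001, 0.5, 0.5, 0.001, 0.001]),
    )


def make_variant_table(
    genotypes,
    pos=None,
    qual=None,
    depth=None,
    alt=None,
    haplotypes=None,
    chrom="1",
):
    """Small VariantTable builder for tests."""
    gt = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = gt.shape
    return VariantTable(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1) * 10 if pos is None else np.asarray(pos),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=[["G"]] * n_sites if alt is None else alt,
        qual=np.full(n_sites, 100.0) if qual is None else np.asarray(qual, float),
        mean_depth=np.full(n_sites, 10.0) if depth is None else np.asarray(depth, float),
        samples=[f"S{i}" for i in range(n_samples)],
        genotypes=gt,
        haplotypes=haplotypes,
    )


@pytest.fixture
def variant_builder():
    return make_variant_table
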