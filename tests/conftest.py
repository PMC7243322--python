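"""Shared fixtures and panel builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from adaptscan.panel import ANC_REF, HaplotypePanel


def build_panel(
    H,
    pos=None,
    chrom="1",
    ref="A",
    alt="G",
    ancestral=None,
    pops=None,
    gmap_cM=None,
):
    """Construct a small valid panel from a haplotype matrix."""
    H = np.asarray(H, dtype=np.int8)
    n_hap, S = H.shape
    assert n_hap % 2 == 0
    n = n_hap // 2
    if pos is None:
        pos = np.arange(1, S + 1) * 100
    if ancestral is None:
        ancestral = np.full(S, ANC_REF, dtype=np.int8)
    if pops is None:
        pops = ["pop1"] * n
    panel = HaplotypePanel(
        chrom=np.array([chrom] * S, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref_allele=np.array([ref] * S, dtype=object),
        alt_allele=np.array([alt] * S, dtype=object),
        H=H,
        sample_ids=[f"s{i:03d}" for i in range(n)],
        pop_labels=list(pops),
        ancestral=np.asarray(ancestral, dtype=np.int8),
        gmap_cM=gmap_cM,
    )
    panel.validate()
    return panel


def random_panel(rng, n_hap=12, n_sites=30, p_missing=0.0, pops=None):
    """Random complete (or partially missing) biallelic panel with mixed
    ancestral orientation."""
    freqs = rng.uniform(0.1, 0.9, n_sites)
    H = (rng.random((n_hap, n_sites)) < freqs).astype(np.int8)
    # keep every site polymorphic for scan-oriented tests
    for j in range(n_sites):
        if H[:, j].sum() == 0:
            H[rng.integers(0, n_hap), j] = 1
        elif H[:, j].sum() == n_hap:
            H[rng.integers(0, n_hap), j] = 0
    if p_missing > 0:
        H[rng.random(H.shape) < p_missing] = -1
    anc = rng.integers(0, 2, n_sites).astype(np.int8)
    return build_panel(H, ancestral=anc, pops=pops)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
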