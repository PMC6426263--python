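"""Shared fixtures: small random datasets and session-scoped simulations."""

import numpy as np
import pytest

from sweepscan.synthetic_data import (PopulationSpec, RelativesSpec, SimConfig,
                                      default_config, simulate_dataset)
from sweepscan.variant_io import HaplotypeSet, VariantTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_dataset(rng):
    """40 haplotypes x 60 sites of random (LD-free) alleles on one chromosome."""
    n_ind, n_sites = 20, 60
    freqs = rng.uniform(0.1, 0.9, n_sites)
    alleles = (rng.random((2 * n_ind, n_sites)) < freqs).astype(np.uint8)
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_sites, replace=False))
    vt = VariantTable(
        chrom=np.asarray(["1"] * n_sites, dtype=object),
        pos=pos,
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(["C"] * n_sites, dtype=object),
        cm=pos * 1e-6,
    )
    haps = HaplotypeSet(alleles, [f"S{i}" for i in range(n_ind)])
    return vt, haps


@pytest.fixture(scope="session")
def neutral_dataset():
    """Three-population neutral forward simulation (the default study shape)."""
    return simulate_dataset(default_config("neutral", seed=42))


@pytest.fixture(scope="session")
def related_dataset():
    """Unlinked panel with injected parent-offspring and full-sib pairs."""
    return simulate_dataset(default_config("related", seed=3))


@pytest.fixture(scope="session")
def small_wf_dataset():
    """Cheap single-population forward simulation for IO/round-trip tests."""
    cfg = SimConfig(
        populations=[PopulationSpec("pop1", 100, sample_size=20)],
        length=200_000, seed=7, maf_min=0.0, preset="custom",
    )
    return simulate_dataset(cfg)
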