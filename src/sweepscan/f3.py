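"""Three-population f3 admixture test with block-jackknife Z-scores.

f3(C; A, B) averages (c - a)(c - b) over SNPs, minus a finite-sample
correction c(1-c)/(n_c - 1) for the sampling variance of the target's
frequency estimate, making the per-site statistic unbiased for the
population-level quantity.  A significantly negative mean (Z <= -3 by the
field's convention) indicates that the target's allele frequencies are
systematically intermediate between the two sources — evidence that C is
admixed between A- and B-related populations.

Standard errors come from a weighted delete-one-block jackknife over
contiguous genomic blocks (default 5 Mb physical), which is robust to LD
between neighbouring SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .allele_stats import FreqTable
from .errors import ConfigurationError, EstimationError
from .variant_io import VariantTable

DEFAULT_BLOCK_MB = 5.0
Z_SIGNIFICANT = -3.0


def f3_snp(a: np.ndarray, b: np.ndarray, c: np.ndarray, n_c: np.ndarray) -> np.ndarray:
    """Per-site unbiased f3 values; sites with n_c < 2 come back as NaN."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    n_c = np.asarray(n_c, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = (c - a) * (c - b) - c * (1.0 - c) / (n_c - 1.0)
    val = np.where(n_c >= 2, val, np.nan)
    return val


def block_jackknife(values: np.ndarray, blocks: np.ndarray):
    """Weighted delete-one-block jackknife mean, SE and Z.

    ``blocks`` assigns a contiguous block label to every value; blocks may
    have unequal sizes (weights are block sizes).  Requires >= 2 non-empty
    blocks; identical leave-one-out means are degenerate (SE = 0) and raise.
    """
    values = np.asarray(values, dtype=np.float64)
    blocks = np.asarray(blocks)
    ok = np.isfinite(values)
    values, blocks = values[ok], blocks[ok]
    labels, inv = np.unique(blocks, return_inverse=True)
    g = len(labels)
    if g < 2:
        raise EstimationError("block jackknife needs >= 2 blocks")
    n = float(len(values))
    m = np.bincount(inv).astype(np.float64)              # block sizes
    sums = np.bincount(inv, weights=values)
    total = values.sum()
    theta = total / n
    theta_del = (total - sums) / (n - m)                 # leave-one-out means
    if np.allclose(theta_del, theta_del[0], atol=0.0, rtol=0.0):
        raise EstimationError("degenerate jackknife: identical blocks")
    h = n / m
    theta_j = g * theta - np.sum((1.0 - m / n) * theta_del)
    var = np.sum((h * theta - (h - 1.0) * theta_del - theta_j) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    if se <= 0:
        raise EstimationError("jackknife SE is zero")
    return float(theta), se, float(theta / se)


def assign_blocks(variants: VariantTable, block_mb: float = DEFAULT_BLOCK_MB) -> np.ndarray:
    """Contiguous physical blocks of ``block_mb`` megabases per chromosome."""
    if block_mb <= 0:
        raise ConfigurationError("block size must be positive")
    size = int(block_mb * 1e6)
    labels = np.empty(len(variants), dtype=object)
    for c in variants.chromosomes():
        sel = variants.chrom_slice(c)
        labels[sel] = [f"{c}:{int(p) // size}" for p in variants.pos[sel]]
    return labels


@dataclass
class F3Result:
    target: str
    source_a: str
    source_b: str
    f3: float
    se: float
    z: float
    n_snps: int
    n_blocks: int

    @property
    def significant(self) -> bool:
        return self.z <= Z_SIGNIFICANT


def f3_test(freq_a: FreqTable, freq_b: FreqTable, freq_c: FreqTable,
            variants: VariantTable, block_mb: float = DEFAULT_BLOCK_MB) -> F3Result:
    """f3(C; A, B) for one triple, with sites dropped test-wise on missingness."""
    ok = (np.isfinite(freq_a.p) & np.isfinite(freq_b.p) & np.isfinite(freq_c.p)
          & (freq_c.n >= 2))
    vals = np.full(len(variants), np.nan)
    vals[ok] = f3_snp(freq_a.p[ok], freq_b.p[ok], freq_c.p[ok], freq_c.n[ok])
    blocks = assign_blocks(variants, block_mb)
    mean, se, z = block_jackknife(vals, blocks)
    n_blocks = len(np.unique(blocks[np.isfinite(vals)]))
    return F3Result(freq_c.population, freq_a.population, freq_b.population,
                    mean, se, z, int(ok.sum()), n_blocks)


def scan_triples(freqs: dict[str, FreqTable], variants: VariantTable,
                 triples: list[tuple[str, str, str]] | None = None,
                 block_mb: float = DEFAULT_BLOCK_MB) -> pd.DataFrame:
    """All (target; sourceA, sourceB) tests, sources unordered.

    ``triples`` entries are (target, sourceA, sourceB); by default every
    population serves as target against every unordered source pair.
    Results are independent of population listing order (sources are
    reported in sorted order).
    """
    pops = sorted(freqs)
    if triples is None:
        if len(pops) < 3:
            raise ConfigurationError("f3 scan needs >= 3 populations")
        triples = [(t, a, b) for t in pops
                   for a, b in combinations([p for p in pops if p != t], 2)]
    rows = []
    for target, a, b in triples:
        a, b = sorted((a, b))
        res = f3_test(freqs[a], freqs[b], freqs[target], variants, block_mb)
        rows.append({
            "target": target, "sourceA": a, "sourceB": b,
            "f3": res.f3, "se": res.se, "z": res.z,
            "n_snps": res.n_snps, "n_blocks": res.n_blocks,
        })
    return pd.DataFrame(rows, columns=["target", "sourceA", "sourceB", "f3",
                                       "se", "z", "n_snps", "n_blocks"])
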