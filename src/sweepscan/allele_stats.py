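"""Allele frequencies, pairwise FST, linkage disequilibrium and LD pruning.

Per-SNP FST defaults to the Hudson estimator in the Bhatia et al. (2013)
ratio form, which is robust to unequal sample sizes; the Reynolds (1983)
coancestry estimator is available for comparability with the original
branch-statistic literature.  Window-level FST is always the ratio of summed
components ("ratio of averages"), never the average of ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, EstimationError
from .variant_io import MISSING, GenotypeSet, HaplotypeSet, PopulationMap

FST_CLAMP = 1.0 - 1e-12


@dataclass
class FreqTable:
    """Alt-allele frequency and haploid sample size per site for one population."""

    population: str
    p: np.ndarray       # alt-allele frequency; NaN where no data
    n: np.ndarray       # non-missing haploid allele count

    def __post_init__(self) -> None:
        ok = self.n > 0
        if np.any((self.p[ok] < 0) | (self.p[ok] > 1)):
            raise EstimationError("allele frequency outside [0,1]")


@dataclass
class FstResult:
    """Per-site FST components for one population pair.

    ``num``/``den`` are the estimator's numerator and denominator; ``fst`` is
    the clamped per-site ratio and ``ok`` marks sites usable downstream
    (den > 0 and both samples informative).
    """

    estimator: str
    num: np.ndarray
    den: np.ndarray
    fst: np.ndarray
    ok: np.ndarray

    def window_fst(self, idx: np.ndarray) -> float:
        """Ratio-of-sums FST over the (usable) sites in *idx*."""
        sel = idx[self.ok[idx]]
        d = self.den[sel].sum()
        if d <= 0:
            raise EstimationError("window FST undefined (denominator <= 0)")
        return float(np.clip(self.num[sel].sum() / d, 0.0, FST_CLAMP))


def allele_freq(genos: GenotypeSet, popmap: PopulationMap, population: str) -> FreqTable:
    """Alt-allele frequency per site in one population (missing-aware)."""
    rows = popmap.indices(genos.samples, population)
    if len(rows) == 0:
        raise ConfigurationError(f"population {population!r} has no genotyped samples")
    d = genos.dosages[rows]
    obs = d != MISSING
    n = 2 * obs.sum(axis=0)
    alt = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return FreqTable(population, p.astype(np.float64), n.astype(np.int64))


def haplotype_freq(haps: HaplotypeSet, popmap: PopulationMap, population: str) -> FreqTable:
    """Alt-allele frequency from phased haplotypes (no missing data)."""
    rows = popmap.indices(haps.samples, population)
    if len(rows) == 0:
        raise ConfigurationError(f"population {population!r} has no samples")
    sub = haps.subset_individuals(rows)
    n = np.full(sub.n_sites, sub.n_haplotypes, dtype=np.int64)
    return FreqTable(population, sub.alleles.mean(axis=0).astype(np.float64), n)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def _hudson_components(p1, n1, p2, n2):
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
           - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _reynolds_components(p1, n1, p2, n2):
    # Reynolds/Weir-Cockerham coancestry in mean-square form for haploid counts.
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r-1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / np.maximum(ntot - 2, 1)
    nc = ntot - (n1 ** 2 + n2 ** 2) / ntot
    num = msp - msg
    den = msp + (nc - 1) * msg
    return num, den


_ESTIMATORS = {"hudson": _hudson_components, "reynolds": _reynolds_components}


def fst_per_snp(f1: FreqTable, f2: FreqTable, estimator: str = "hudson") -> FstResult:
    """Per-site FST components between two populations.

    Sites with fewer than 2 haploid observations in either sample, or with a
    non-positive denominator (jointly monomorphic), are flagged unusable.
    Negative per-site estimates are clamped to 0 and estimates of 1 to
    ``1 - 1e-12`` so the branch-length transform stays finite.
    """
    if estimator not in _ESTIMATORS:
        raise ConfigurationError(f"unknown FST estimator {estimator!r}")
    p1 = f1.p.astype(np.float64)
    p2 = f2.p.astype(np.float64)
    n1 = f1.n.astype(np.float64)
    n2 = f2.n.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        num, den = _ESTIMATORS[estimator](p1, n1, p2, n2)
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(num) & np.isfinite(den) & (den > 0)
    fst = np.full_like(p1, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = num / den
    fst[ok] = np.clip(ratio[ok], 0.0, FST_CLAMP)
    return FstResult(estimator, num, den, fst, ok)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def r2_genotype(dos_i: np.ndarray, dos_j: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    ok = (dos_i != MISSING) & (dos_j != MISSING)
    x = dos_i[ok].astype(np.float64)
    y = dos_j[ok].astype(np.float64)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        raise EstimationError("r2 undefined for monomorphic/empty site pair")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def r2_haplotype(hap_i: np.ndarray, hap_j: np.ndarray) -> float:
    """Haplotype r^2 = D^2 / (pA pa pB pb) from phased 0/1 columns."""
    pa = hap_i.mean()
    pb = hap_j.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise EstimationError("r2 undefined for monomorphic site")
    pab = np.mean((hap_i == 1) & (hap_j == 1))
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def ld_prune(genos: GenotypeSet, r2_max: float = 0.4, window: int = 50,
             step: int = 10, variants=None) -> np.ndarray:
    """Greedy windowed LD pruning; returns indices of retained sites.

    Mirrors the classic genotype-r2 pruning rule: within each window of
    ``window`` sites, for every pair exceeding ``r2_max`` the *later* site is
    dropped; the window then shifts by ``step`` sites.  Windows never span
    chromosomes.  The post-condition (no retained pair within a window above
    the threshold) is what downstream structure analyses assume.
    """
    d = genos.dosages.astype(np.float64)
    d[genos.dosages == MISSING] = np.nan
    n_sites = d.shape[1]
    keep = np.ones(n_sites, dtype=bool)

    if variants is not None:
        chrom_groups = [variants.chrom_slice(c) for c in variants.chromosomes()]
    else:
        chrom_groups = [np.arange(n_sites)]

    col_mean = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_mean[None, :], d)
    centered = filled - filled.mean(axis=0)
    norms = np.sqrt((centered ** 2).sum(axis=0))

    for sites in chrom_groups:
        start = 0
        while start < len(sites):
            win = sites[start:start + window]
            active = win[keep[win]]
            mono = norms[active] == 0
            a = active[~mono]
            if len(a) > 1:
                block = centered[:, a]
                nrm = norms[a]
                corr = (block.T @ block) / np.outer(nrm, nrm)
                r2 = corr ** 2
                for jj in range(1, len(a)):
                    if not keep[a[jj]]:
                        continue
                    for ii in range(jj):
                        if keep[a[ii]] and r2[ii, jj] > r2_max:
                            keep[a[jj]] = False  # drop the later site
                            break
            if start + window >= len(sites):
                break
            start += step
    return np.flatnonzero(keep)
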