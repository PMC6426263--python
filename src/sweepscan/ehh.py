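"""Extended haplotype homozygosity (EHH), its integral (iHH), and xpEHH.

EHH at extension site x is the probability that two randomly drawn
haplotypes are identical over every site from the core to x inclusive,
given that they are identical at the core:

    EHH(x) = sum_h C(c_h, 2) / sum_a C(c_a, 2)

with c_h the identical-haplotype class sizes over [core, x] and c_a the
core-allele class sizes, so EHH(0) = 1 exactly and the decay curve is not
confounded by the core site's own allele frequency (the site-homozygosity
normalization of the published cross-population statistic).  For the
cross-population
statistic the EHH is computed over *all* haplotypes of a population
(site-EHH), the decay curve is truncated where EHH drops below a cutoff
(default 0.05), and the integral over physical (or genetic) distance gives
iHH.  xpEHH = ln(iHH_focal / iHH_other), standardized genome-wide; positive
values mean unusually long haplotype homozygosity in the focal population —
the footprint of a recent sweep.

Cores whose extension reaches a chromosome edge, or crosses an inter-site
gap larger than ``max_gap`` (default 200 kb), before hitting the cutoff are
flagged and excluded from standardization, mirroring common rehh practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError
from .variant_io import HaplotypeSet, VariantTable

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000


@dataclass
class EHHProfile:
    core: int                   # global site index
    direction: int              # +1 right, -1 left
    sites: np.ndarray           # site indices from core outward (core first)
    distances: np.ndarray       # |coordinate - core coordinate|, same length
    ehh: np.ndarray             # EHH values; ehh[0] == 1
    reason: str                 # 'cutoff' | 'edge' | 'gap'


def _pairs(counts: np.ndarray) -> float:
    return float((counts * (counts - 1)).sum() / 2.0)


def ehh_profile(haps: HaplotypeSet, variants: VariantTable, core: int,
                direction: int, cutoff: float = DEFAULT_CUTOFF,
                max_gap: int = DEFAULT_MAX_GAP, use_cm: bool = False) -> EHHProfile:
    """EHH decay curve from one core site in one direction.

    The value at distance 0 is 1 by definition (normalization by the pairs
    already identical at the core).  Extension stops at the first site with
    EHH < ``cutoff`` ('cutoff'), at the chromosome edge ('edge'), or when a
    physical gap > ``max_gap`` bp is crossed ('gap').
    """
    n = haps.n_haplotypes
    if n < 2:
        raise EstimationError("EHH needs at least two haplotypes")
    coord = variants.cm if (use_cm and variants.cm is not None) else variants.pos
    chrom_sites = variants.chrom_slice(str(variants.chrom[core]))
    lo, hi = chrom_sites[0], chrom_sites[-1]

    ids = haps.alleles[:, core].astype(np.int64)
    denom = _pairs(np.bincount(ids))
    if denom == 0:
        raise EstimationError("no identical haplotype pair at the core")
    sites = [core]
    dists = [0.0]
    vals = [1.0]
    reason = "edge"
    j = core
    while True:
        nxt = j + direction
        if nxt < lo or nxt > hi:
            reason = "edge"
            break
        if abs(int(variants.pos[nxt]) - int(variants.pos[j])) > max_gap:
            reason = "gap"
            break
        ids = ids * 2 + haps.alleles[:, nxt]
        _, ids = np.unique(ids, return_inverse=True)
        counts = np.bincount(ids)
        e = _pairs(counts) / denom
        if e < cutoff:
            reason = "cutoff"
            break
        sites.append(nxt)
        dists.append(abs(float(coord[nxt]) - float(coord[core])))
        vals.append(e)
        j = nxt
    return EHHProfile(core, direction, np.asarray(sites), np.asarray(dists),
                      np.asarray(vals), reason)


def ihh(left: EHHProfile, right: EHHProfile, cutoff: float = DEFAULT_CUTOFF):
    """Trapezoidal integral of EHH over both directions.

    Returns ``(value, flagged)``; a core is flagged when either direction
    ended at a chromosome edge or crossed a large gap before reaching the
    cutoff, because its integral is then censored.
    """
    flagged = left.reason != "cutoff" or right.reason != "cutoff"
    total = 0.0
    for prof in (left, right):
        if len(prof.distances) > 1:
            total += float(np.trapezoid(prof.ehh, prof.distances))
    return total, flagged


def ihh_at(haps: HaplotypeSet, variants: VariantTable, core: int,
           cutoff: float = DEFAULT_CUTOFF, max_gap: int = DEFAULT_MAX_GAP,
           use_cm: bool = False):
    left = ehh_profile(haps, variants, core, -1, cutoff, max_gap, use_cm)
    right = ehh_profile(haps, variants, core, +1, cutoff, max_gap, use_cm)
    return ihh(left, right, cutoff)


def xpehh_scan(haps_a: HaplotypeSet, haps_b: HaplotypeSet, variants: VariantTable,
               cores: np.ndarray | None = None, cutoff: float = DEFAULT_CUTOFF,
               max_gap: int = DEFAULT_MAX_GAP, use_cm: bool = False) -> pd.DataFrame:
    """xpEHH over core sites; A is the focal population.

    Cores default to all sites polymorphic in both populations.  Raw values
    are ln(iHH_A / iHH_B); standardization (mean 0, sd 1) is global over all
    unflagged cores.  A core is flagged if either population's profile is
    edge/gap-censored or either iHH is zero.
    """
    pa = haps_a.alleles.mean(axis=0)
    pb = haps_b.alleles.mean(axis=0)
    if cores is None:
        cores = np.flatnonzero((pa > 0) & (pa < 1) & (pb > 0) & (pb < 1))
    cores = np.asarray(cores, dtype=np.int64)

    ihh_a = np.full(len(cores), np.nan)
    ihh_b = np.full(len(cores), np.nan)
    flagged = np.zeros(len(cores), dtype=bool)
    for k, c in enumerate(cores):
        poly_a = 0 < pa[c] < 1
        poly_b = 0 < pb[c] < 1
        if not (poly_a and poly_b):
            flagged[k] = True
            continue
        va, fa = ihh_at(haps_a, variants, int(c), cutoff, max_gap, use_cm)
        vb, fb = ihh_at(haps_b, variants, int(c), cutoff, max_gap, use_cm)
        ihh_a[k], ihh_b[k] = va, vb
        flagged[k] = fa or fb or va <= 0 or vb <= 0

    raw = np.full(len(cores), np.nan)
    usable = ~flagged
    with np.errstate(divide="ignore", invalid="ignore"):
        # difference of logs (not log of ratio) so that swapping the two
        # populations negates the statistic bit-exactly
        raw[usable] = np.log(ihh_a[usable]) - np.log(ihh_b[usable])
    std = np.full(len(cores), np.nan)
    if usable.sum() >= 2:
        mu = raw[usable].mean()
        sd = raw[usable].std()
        if sd > 0:
            std[usable] = (raw[usable] - mu) / sd
    return pd.DataFrame({
        "site_idx": cores,
        "chrom": variants.chrom[cores],
        "pos": variants.pos[cores],
        "ihh_a": ihh_a,
        "ihh_b": ihh_b,
        "raw": raw,
        "std": std,
        "flagged": flagged,
    })
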