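"""Population branch statistic (PBS): per-SNP values, windowed scan, outliers.

The PBS measures allele-frequency differentiation specific to a focal
population A against a sister group B and an outgroup/reference C.  Pairwise
FST values are transformed to branch lengths T = -log(1 - FST) and the focal
branch is

    PBS = (T_AB + T_AC - T_BC) / 2

Elevated values mark lineage-specific drift or positive selection in A.
The scan averages per-SNP PBS in sliding windows of ``window_size`` SNPs in
which consecutive windows share ``shared`` SNPs (stride = window_size -
shared); outliers are windows above an empirical percentile of the
genome-wide window means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allele_stats import FreqTable, FstResult, fst_per_snp
from .errors import ConfigurationError
from .variant_io import VariantTable

logger = logging.getLogger(__name__)


def branch_length(fst) -> np.ndarray:
    """T = -log(1 - FST); requires FST in [0, 1).  Vectorized."""
    fst = np.asarray(fst, dtype=np.float64)
    if np.any(fst[np.isfinite(fst)] >= 1.0):
        raise ConfigurationError("FST >= 1 must be clamped before the transform")
    if np.any(fst[np.isfinite(fst)] < 0.0):
        raise ConfigurationError("negative FST must be clamped before the transform")
    return -np.log1p(-fst)


def pbs_snp(t_ab, t_ac, t_bc) -> np.ndarray:
    """Focal branch length from three pairwise branch lengths; may be negative."""
    t_ab = np.asarray(t_ab, dtype=np.float64)
    return (t_ab + np.asarray(t_ac) - np.asarray(t_bc)) / 2.0


@dataclass
class PBSScan:
    """Per-site PBS values plus the windowed scan table."""

    variants: VariantTable
    t_ab: np.ndarray
    t_ac: np.ndarray
    t_bc: np.ndarray
    values: np.ndarray          # per-SNP PBS; NaN where any FST undefined
    ok: np.ndarray              # sites entering windows
    windows: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def pbs_per_snp(freq_a: FreqTable, freq_b: FreqTable, freq_c: FreqTable,
                variants: VariantTable, estimator: str = "hudson") -> PBSScan:
    """Per-SNP PBS for focal A, sister B, reference C.

    Sites where any of the three pairwise FST values is undefined are
    excluded from windows (flagged in ``ok``).
    """
    f_ab = fst_per_snp(freq_a, freq_b, estimator)
    f_ac = fst_per_snp(freq_a, freq_c, estimator)
    f_bc = fst_per_snp(freq_b, freq_c, estimator)
    ok = f_ab.ok & f_ac.ok & f_bc.ok
    t_ab = np.full(len(variants), np.nan)
    t_ac = np.full(len(variants), np.nan)
    t_bc = np.full(len(variants), np.nan)
    t_ab[ok] = branch_length(f_ab.fst[ok])
    t_ac[ok] = branch_length(f_ac.fst[ok])
    t_bc[ok] = branch_length(f_bc.fst[ok])
    values = pbs_snp(t_ab, t_ac, t_bc)
    return PBSScan(variants, t_ab, t_ac, t_bc, values, ok)


def window_scan(scan: PBSScan, window_size: int = 20, shared: int = 5) -> pd.DataFrame:
    """Sliding-window means of per-SNP PBS.

    Windows are defined over the usable sites of each chromosome; consecutive
    windows share ``shared`` sites and the trailing partial window is
    dropped.  Chromosomes with fewer than ``window_size`` usable sites are
    skipped with a warning.
    """
    if not 0 <= shared < window_size:
        raise ConfigurationError("need 0 <= shared < window_size")
    stride = window_size - shared
    rows = []
    vt = scan.variants
    for c in vt.chromosomes():
        sites = vt.chrom_slice(c)
        usable = sites[scan.ok[sites]]
        if len(usable) < window_size:
            warnings.warn(f"chromosome {c}: fewer than {window_size} usable sites; skipped")
            continue
        for start in range(0, len(usable) - window_size + 1, stride):
            w = usable[start:start + window_size]
            vals = scan.values[w]
            imax = int(np.argmax(vals))  # ties -> smallest position (first index)
            rows.append({
                "chrom": c,
                "start_idx": int(w[0]), "end_idx": int(w[-1]),
                "start_bp": int(vt.pos[w[0]]), "end_bp": int(vt.pos[w[-1]]),
                "n_snps": window_size,
                "mean_pbs": float(vals.mean()),
                "index_idx": int(w[imax]),
                "index_id": str(vt.ids[w[imax]]),
                "index_pos": int(vt.pos[w[imax]]),
                "index_pbs": float(vals[imax]),
            })
    df = pd.DataFrame(rows, columns=[
        "chrom", "start_idx", "end_idx", "start_bp", "end_bp", "n_snps",
        "mean_pbs", "index_idx", "index_id", "index_pos", "index_pbs"])
    scan.windows = df
    return df


def outlier_windows(windows: pd.DataFrame, percentile: float = 99.9):
    """Windows with mean PBS at or above the empirical percentile.

    Returns ``(outlier DataFrame, threshold value)``.  With fewer than 1000
    windows the default percentile is poorly resolved and a warning is
    emitted; a degenerate all-equal scan yields an empty outlier set.
    """
    if len(windows) == 0:
        return windows.iloc[0:0], np.nan
    if len(windows) < 1000 and percentile >= 99.9:
        warnings.warn(f"only {len(windows)} windows; {percentile}th percentile is coarse")
    means = windows["mean_pbs"].to_numpy()
    thr = float(np.percentile(means, percentile))  # linear-interpolation quantile
    if np.all(means == means[0]):
        warnings.warn("all window means equal; returning no outliers")
        return windows.iloc[0:0], thr
    return windows[means >= thr], thr


def index_snp(scan: PBSScan, site_indices: np.ndarray) -> int:
    """Site (global index) with maximal per-SNP PBS in a region; ties -> smallest pos."""
    site_indices = np.asarray(site_indices, dtype=np.int64)
    if len(site_indices) == 0:
        raise ConfigurationError("empty region")
    vals = scan.values[site_indices]
    best = np.nanmax(vals)
    cands = site_indices[vals == best]
    return int(cands[np.argmin(scan.variants.pos[cands])])
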