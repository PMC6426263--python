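"""Candidate selection regions: PBS outlier windows corroborated by xpEHH.

A window qualifies when its mean PBS reaches the outlier percentile AND it
contains at least one (unflagged) site with standardized xpEHH above the
threshold.  Qualifying windows that share sites are merged; the merged
region's index SNP is the site with the maximal per-SNP PBS.  Regions then
receive an empirical p-value against the simulated window-level neutral
null and, optionally, a nearest-gene annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import empirical_pvalue
from .errors import ConfigurationError
from .pbs import PBSScan, index_snp, outlier_windows
from .variant_io import GeneTable

logger = logging.getLogger(__name__)

DEFAULT_PBS_PERCENTILE = 99.9
DEFAULT_XPEHH_MIN = 2.0
DEFAULT_P_SIGNIFICANT = 0.05


@dataclass
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    start_idx: int
    end_idx: int
    index_idx: int
    index_id: str
    index_pos: int
    index_pbs: float
    mean_pbs: float          # max member-window mean
    max_xpehh: float
    p_value: float = np.nan
    significant: bool = False
    nearest_gene: str = ""
    gene_distance: int = -1


def call_candidates(scan: PBSScan, xpehh: pd.DataFrame,
                    pbs_percentile: float = DEFAULT_PBS_PERCENTILE,
                    xpehh_min: float = DEFAULT_XPEHH_MIN,
                    merge_gap: int = 0) -> list[CandidateRegion]:
    """Intersect PBS outlier windows with xpEHH evidence and merge.

    ``merge_gap`` merges qualifying windows whose site-index ranges come
    within that many sites of each other (0 = share/abut).  Flagged xpEHH
    cores never qualify a window.
    """
    if scan.windows is None or len(scan.windows) == 0:
        return []
    outliers, _thr = outlier_windows(scan.windows, pbs_percentile)
    if len(outliers) == 0:
        return []
    good = xpehh[~xpehh["flagged"].astype(bool) & (xpehh["std"] > xpehh_min)]
    hit_sites = set(good["site_idx"].astype(int))
    qual = []
    for _, w in outliers.iterrows():
        members = range(int(w["start_idx"]), int(w["end_idx"]) + 1)
        if any(s in hit_sites for s in members):
            qual.append(w)
    if not qual:
        return []
    qual.sort(key=lambda w: (str(w["chrom"]), int(w["start_idx"])))
    merged: list[list] = []
    for w in qual:
        if merged and merged[-1][0] == str(w["chrom"]) \
                and int(w["start_idx"]) <= merged[-1][2] + 1 + merge_gap:
            merged[-1][2] = max(merged[-1][2], int(w["end_idx"]))
            merged[-1][3] = max(merged[-1][3], float(w["mean_pbs"]))
        else:
            merged.append([str(w["chrom"]), int(w["start_idx"]), int(w["end_idx"]),
                           float(w["mean_pbs"])])
    regions = []
    vt = scan.variants
    xp_by_site = dict(zip(xpehh["site_idx"].astype(int), xpehh["std"]))
    xp_flag = dict(zip(xpehh["site_idx"].astype(int), xpehh["flagged"].astype(bool)))
    for chrom, s_idx, e_idx, mean_pbs in merged:
        sites = np.arange(s_idx, e_idx + 1)
        sites = sites[scan.ok[sites]]
        idx = index_snp(scan, sites)
        xps = [xp_by_site[s] for s in sites
               if s in xp_by_site and not xp_flag[s] and np.isfinite(xp_by_site[s])]
        regions.append(CandidateRegion(
            chrom=chrom,
            start_bp=int(vt.pos[s_idx]), end_bp=int(vt.pos[e_idx]),
            start_idx=int(s_idx), end_idx=int(e_idx),
            index_idx=int(idx), index_id=str(vt.ids[idx]),
            index_pos=int(vt.pos[idx]), index_pbs=float(scan.values[idx]),
            mean_pbs=mean_pbs,
            max_xpehh=float(max(xps)) if xps else np.nan,
        ))
    return regions


def top_window_region(windows: pd.DataFrame) -> tuple[str, int, int]:
    """Span of the top-ranked window after merging with overlapping windows.

    The genome-wide best window by mean PBS is extended by every window that
    shares sites with it (transitively), the same adjacency rule used when
    candidate regions are merged.  Returns ``(chrom, start_bp, end_bp)``.
    """
    if len(windows) == 0:
        raise ConfigurationError("empty window table")
    top = windows.loc[windows["mean_pbs"].idxmax()]
    chrom = str(top["chrom"])
    s, e = int(top["start_idx"]), int(top["end_idx"])
    same = windows[windows["chrom"].astype(str) == chrom]
    changed = True
    while changed:
        changed = False
        for _, w in same.iterrows():
            ws, we = int(w["start_idx"]), int(w["end_idx"])
            if ws <= e and we >= s and (ws < s or we > e):
                s, e = min(s, ws), max(e, we)
                changed = True
    sel_s = same[same["start_idx"] == s]
    sel_e = same[same["end_idx"] == e]
    return chrom, int(sel_s["start_bp"].iloc[0]), int(sel_e["end_bp"].iloc[0])


def attach_pvalues(regions: list[CandidateRegion], null_window: np.ndarray,
                   p_significant: float = DEFAULT_P_SIGNIFICANT) -> list[CandidateRegion]:
    """Empirical p-value of each region's window-mean PBS vs the neutral null."""
    if null_window is None or len(null_window) == 0:
        raise ConfigurationError("window-level null distribution required")
    for r in regions:
        r.p_value = empirical_pvalue(r.mean_pbs, null_window)
        r.significant = r.p_value < p_significant
    return regions


def nearest_gene(region: CandidateRegion, genes: GeneTable):
    """Closest gene to a region; distance 0 when overlapping.

    Regions are 1-based inclusive [start_bp, end_bp]; genes are BED
    half-open [start, end).  Ties go to the smaller gene start.
    """
    if len(genes) == 0:
        logger.warning("empty gene table; annotation skipped")
        return None, -1
    same = genes.chrom.astype(str) == region.chrom
    if not same.any():
        return None, -1
    g_start1 = genes.start[same] + 1          # 1-based inclusive gene span
    g_end1 = genes.end[same]
    names = genes.name[same]
    gap_left = g_start1 - region.end_bp       # gene right of region
    gap_right = region.start_bp - g_end1      # gene left of region
    dist = np.maximum(np.maximum(gap_left, gap_right), 0)
    order = np.lexsort((genes.start[same], dist))
    best = order[0]
    return str(names[best]), int(dist[best])


def annotate_regions(regions: list[CandidateRegion], genes: GeneTable) -> list[CandidateRegion]:
    for r in regions:
        g, d = nearest_gene(r, genes)
        r.nearest_gene = g or ""
        r.gene_distance = d
    return regions


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = [{
        "chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
        "index_id": r.index_id, "index_pos": r.index_pos,
        "index_pbs": r.index_pbs, "mean_pbs": r.mean_pbs,
        "max_xpehh": r.max_xpehh, "p_value": r.p_value,
        "significant": r.significant,
        "nearest_gene": r.nearest_gene, "gene_distance": r.gene_distance,
    } for r in regions]
    return pd.DataFrame(rows, columns=[
        "chrom", "start_bp", "end_bp", "index_id", "index_pos", "index_pbs",
        "mean_pbs", "max_xpehh", "p_value", "significant", "nearest_gene",
        "gene_distance"])


def regions_to_bed(regions: list[CandidateRegion], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.index_id}\n")
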