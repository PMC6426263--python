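"""End-to-end orchestration: relatedness pruning, scans, null calibration,
candidate calling and the f3 sweep over population triples.

Every threshold and estimator choice used by a run is logged to
``run_header.txt`` in the report directory so a report is self-describing.
Outputs are plain TSV with fixed float formatting; a rerun with the same
inputs and seed is byte-identical.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allele_stats import haplotype_freq, ld_prune
from .coalescent import DEFAULT_MS_COMMAND, parse_ms_command, pbs_null
from .ehh import xpehh_scan
from .errors import ConfigurationError
from .f3 import scan_triples
from .pbs import outlier_windows, pbs_per_snp, window_scan
from .regions import (annotate_regions, attach_pvalues, call_candidates,
                      regions_to_bed, regions_to_frame)
from .relatedness import (DEFAULT_PHI_THRESHOLD, build_family_network,
                          estimate_kinship, prune_related)
from .variant_io import (interpolate_cm, read_gene_bed, read_genetic_map,
                         read_population_map, read_vcf)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Structured configuration for a full run (YAML-loadable)."""

    vcf: str = ""
    popmap: str = ""
    genetic_map: str | None = None
    genes_bed: str | None = None
    out_dir: str = "sweepscan_report"
    # population roles
    focal: str = "focal"
    sister: str = "sister"
    reference: str = "reference"
    xpehh_comparator: str | None = None    # defaults to the sister group
    exclude_samples: list[str] = field(default_factory=list)
    # thresholds (the published defaults)
    phi_threshold: float = DEFAULT_PHI_THRESHOLD
    kinship_min_sites: int = 200
    ld_r2_max: float = 0.4
    ld_window: int = 50
    ld_step: int = 10
    window_size: int = 20
    window_shared: int = 5
    pbs_percentile: float = 99.9
    xpehh_min: float = 2.0
    f3_z: float = -3.0
    p_significant: float = 0.05
    f3_block_mb: float = 5.0
    estimator: str = "hudson"
    ehh_cutoff: float = 0.05
    ehh_max_gap: int = 200_000
    use_cm: bool = False
    run_ld_prune: bool = False
    run_f3: bool = True
    # null model
    ms_command: str = DEFAULT_MS_COMMAND
    null_roles: tuple[int, int, int] = (0, 2, 1)
    reps: int = 10_000
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.null_roles = tuple(cfg.null_roles)
        return cfg


def _write(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns a bundle of in-memory results.

    Stage order: sample exclusion -> relatedness pruning -> (optional) LD
    pruning list -> PBS scan -> xpEHH scan -> neutral null simulation ->
    candidate calling (+ p-values, nearest genes) -> f3 scan.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    vt, genos, haps, samples = read_vcf(cfg.vcf, require_phased=True)
    popmap = read_population_map(cfg.popmap)
    if cfg.genetic_map:
        vt = interpolate_cm(vt, read_genetic_map(cfg.genetic_map))

    if cfg.exclude_samples:
        keep = np.asarray([i for i, s in enumerate(samples)
                           if s not in set(cfg.exclude_samples)], dtype=np.int64)
        haps = haps.subset_individuals(keep)
        samples = haps.samples

    # relatedness pruning, per population with within-population frequencies
    genos = haps.to_genotypes()
    kin_frames, f_frames, removed = [], [], []
    for pop in popmap.populations():
        rows = popmap.indices(samples, pop)
        if len(rows) < 2:
            continue
        freqs = haplotype_freq(haps, popmap, pop)
        kin = estimate_kinship(genos, freqs, rows, min_sites=cfg.kinship_min_sites)
        kin_frames.append(kin.pairs)
        f_frames.append(kin.inbreeding)
        removed.extend(prune_related(build_family_network(kin, cfg.phi_threshold)))
    kin_pairs = pd.concat(kin_frames, ignore_index=True) if kin_frames else pd.DataFrame()
    kin_f = pd.concat(f_frames, ignore_index=True) if f_frames else pd.DataFrame()
    if removed:
        keep = np.asarray([i for i, s in enumerate(samples) if s not in set(removed)],
                          dtype=np.int64)
        haps = haps.subset_individuals(keep)
        samples = haps.samples
        genos = haps.to_genotypes()

    kept_ld = None
    if cfg.run_ld_prune:
        kept_ld = ld_prune(genos, cfg.ld_r2_max, cfg.ld_window, cfg.ld_step, vt)

    freqs = {p: haplotype_freq(haps, popmap, p) for p in popmap.populations()}
    for role in (cfg.focal, cfg.sister, cfg.reference):
        if role not in freqs:
            raise ConfigurationError(f"role population {role!r} not in data")

    scan = pbs_per_snp(freqs[cfg.focal], freqs[cfg.sister], freqs[cfg.reference],
                       vt, cfg.estimator)
    windows = window_scan(scan, cfg.window_size, cfg.window_shared)
    _outliers, pbs_threshold = outlier_windows(windows, cfg.pbs_percentile)

    comparator = cfg.xpehh_comparator or cfg.sister
    pops_idx = {p: popmap.indices(samples, p) for p in (cfg.focal, comparator)}
    xp = xpehh_scan(haps.subset_individuals(pops_idx[cfg.focal]),
                    haps.subset_individuals(pops_idx[comparator]),
                    vt, cutoff=cfg.ehh_cutoff, max_gap=cfg.ehh_max_gap,
                    use_cm=cfg.use_cm)

    model = parse_ms_command(cfg.ms_command)
    null = pbs_null(model, roles=cfg.null_roles, reps=cfg.reps,
                    window_size=cfg.window_size, estimator=cfg.estimator,
                    seed=cfg.seed)

    cands = call_candidates(scan, xp, cfg.pbs_percentile, cfg.xpehh_min)
    cands = attach_pvalues(cands, null.window, cfg.p_significant)
    genes = None
    if cfg.genes_bed:
        genes = read_gene_bed(cfg.genes_bed)
        cands = annotate_regions(cands, genes)
    cand_df = regions_to_frame(cands)

    f3_df = pd.DataFrame()
    if cfg.run_f3 and len(popmap.populations()) >= 3:
        span_mb = sum((vt.pos[vt.chrom_slice(c)].max() - vt.pos[vt.chrom_slice(c)].min())
                      for c in vt.chromosomes()) / 1e6
        block_mb = cfg.f3_block_mb
        if span_mb / block_mb < 10:
            block_mb = max(span_mb / 10.0, 1e-6)
            warnings.warn(f"short input ({span_mb:.1f} Mb): f3 jackknife blocks "
                          f"shrunk to {block_mb:.3f} Mb")
        f3_df = scan_triples(freqs, vt, block_mb=block_mb)

    # ---- report bundle -------------------------------------------------
    _write(kin_pairs, os.path.join(cfg.out_dir, "kinship.tsv"))
    _write(kin_f, os.path.join(cfg.out_dir, "inbreeding.tsv"))
    with open(os.path.join(cfg.out_dir, "removed_samples.txt"), "w") as fh:
        fh.writelines(f"{s}\n" for s in removed)
    if kept_ld is not None:
        with open(os.path.join(cfg.out_dir, "ld_kept_sites.txt"), "w") as fh:
            fh.writelines(f"{vt.ids[i]}\n" for i in kept_ld)
    snp_df = pd.DataFrame({
        "chrom": vt.chrom, "pos": vt.pos, "id": vt.ids,
        "t_ab": scan.t_ab, "t_ac": scan.t_ac, "t_bc": scan.t_bc,
        "pbs": scan.values, "ok": scan.ok,
    })
    _write(snp_df, os.path.join(cfg.out_dir, "pbs_snp.tsv"))
    _write(windows, os.path.join(cfg.out_dir, "pbs_windows.tsv"))
    _write(xp, os.path.join(cfg.out_dir, "xpehh.tsv"))
    _write(pd.DataFrame({"window_null_pbs": null.window}),
           os.path.join(cfg.out_dir, "null_pbs_window.tsv"))
    _write(cand_df, os.path.join(cfg.out_dir, "candidates.tsv"))
    regions_to_bed(cands, os.path.join(cfg.out_dir, "candidates.bed"))
    if len(f3_df):
        _write(f3_df, os.path.join(cfg.out_dir, "f3.tsv"))

    with open(os.path.join(cfg.out_dir, "run_header.txt"), "w") as fh:
        fh.write(f"sweepscan {__version__}\n")
        fh.write(f"fst_estimator\t{cfg.estimator}\n")
        fh.write(f"window\t{cfg.window_size} SNPs, consecutive windows share "
                 f"{cfg.window_shared} SNPs (stride {cfg.window_size - cfg.window_shared})\n")
        fh.write(f"pbs_percentile\t{cfg.pbs_percentile}\n")
        fh.write(f"pbs_window_threshold\t{pbs_threshold:.10g}\n")
        fh.write(f"xpehh_min\t{cfg.xpehh_min}\n")
        fh.write(f"xpehh_distance_unit\t{'cM' if cfg.use_cm else 'bp'}\n")
        fh.write(f"xpehh_comparator\t{comparator}\n")
        fh.write(f"phi_threshold\t{cfg.phi_threshold}\n")
        fh.write(f"pvalue_convention\t(1+k)/(1+n) upper tail\n")
        fh.write(f"ms_command\t{cfg.ms_command}\n")
        fh.write(f"null_reps\t{cfg.reps}\tredrawn\t{null.n_redrawn}\n")
        fh.write(f"seed\t{cfg.seed}\n")
        fh.write(f"excluded_samples\t{len(cfg.exclude_samples)}\n")
        fh.write(f"pruned_related\t{len(removed)}\n")

    return {
        "variants": vt, "haplotypes": haps, "popmap": popmap,
        "kinship": kin_pairs, "inbreeding": kin_f, "removed": removed,
        "scan": scan, "windows": windows, "pbs_threshold": pbs_threshold,
        "xpehh": xp, "null": null, "candidates": cands,
        "candidates_frame": cand_df, "f3": f3_df,
    }
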