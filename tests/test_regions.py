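import numpy as np
import pandas as pd
import pytest

from sweepscan.errors import ConfigurationError
from sweepscan.pbs import PBSScan, window_scan
from sweepscan.regions import (annotate_regions, attach_pvalues,
                               call_candidates, nearest_gene, regions_to_frame)
from sweepscan.variant_io import GeneTable, VariantTable


def _vt(n, spacing=1000):
    pos = (np.arange(n) + 1) * spacing
    return VariantTable(chrom=np.asarray(["1"] * n, dtype=object), pos=pos,
                        ref=np.asarray(["A"] * n, dtype=object),
                        alt=np.asarray(["C"] * n, dtype=object))


def _scan_with_windows(values):
    values = np.asarray(values, dtype=float)
    vt = _vt(len(values))
    t = np.zeros_like(values)
    scan = PBSScan(vt, t, t, t, values, np.ones(len(values), dtype=bool))
    window_scan(scan)
    return scan


def _xpehh(n, std_values, flagged=None):
    flagged = np.zeros(n, dtype=bool) if flagged is None else flagged
    return pd.DataFrame({
        "site_idx": np.arange(n),
        "chrom": ["1"] * n,
        "pos": (np.arange(n) + 1) * 1000,
        "ihh_a": np.ones(n), "ihh_b": np.ones(n),
        "raw": np.zeros(n), "std": std_values, "flagged": flagged,
    })


def _spiked(n=2000, at=1000):
    vals = np.zeros(n)
    vals[at] = 10.0
    return vals, at


class TestCallCandidates:
    def test_no_xpehh_support_means_no_candidates(self):
        vals, at = _spiked()
        scan = _scan_with_windows(vals)
        xp = _xpehh(len(vals), np.zeros(len(vals)))
        assert call_candidates(scan, xp, 99.0, 2.0) == []

    def test_spiked_locus_with_support_gives_one_region_containing_it(self):
        vals, at = _spiked()
        scan = _scan_with_windows(vals)
        std = np.zeros(len(vals))
        std[at] = 5.0
        regions = call_candidates(scan, _xpehh(len(vals), std), 99.0, 2.0)
        assert len(regions) == 1
        r = regions[0]
        assert r.start_idx <= at <= r.end_idx
        assert r.index_idx == at
        assert r.max_xpehh == pytest.approx(5.0)

    def test_flagged_xpehh_sites_never_qualify(self):
        vals, at = _spiked()
        scan = _scan_with_windows(vals)
        std = np.zeros(len(vals))
        std[at] = 5.0
        flagged = np.zeros(len(vals), dtype=bool)
        flagged[at] = True
        assert call_candidates(scan, _xpehh(len(vals), std, flagged), 99.0, 2.0) == []

    def test_merging_matches_interval_union_oracle(self, rng):
        # qualifying windows are those overlapping high-PBS stretches
        vals = np.zeros(3000)
        vals[900:960] = 8.0   # spans several overlapping windows
        scan = _scan_with_windows(vals)
        std = np.full(len(vals), 5.0)
        regions = call_candidates(scan, _xpehh(len(vals), std), 98.0, 2.0)
        # oracle: union of qualifying window index ranges
        from sweepscan.pbs import outlier_windows
        out, _ = outlier_windows(scan.windows, 98.0)
        ivs = sorted((int(w["start_idx"]), int(w["end_idx"])) for _, w in out.iterrows())
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        assert [(r.start_idx, r.end_idx) for r in regions] == \
               [tuple(m) for m in merged]

    def test_candidate_count_monotone_in_thresholds(self):
        vals, at = _spiked()
        vals[500] = 6.0
        scan = _scan_with_windows(vals)
        std = np.full(len(vals), 3.0)
        loose = call_candidates(scan, _xpehh(len(vals), std), 95.0, 2.0)
        tight_pbs = call_candidates(scan, _xpehh(len(vals), std), 99.9, 2.0)
        tight_xp = call_candidates(scan, _xpehh(len(vals), std), 95.0, 4.0)
        assert len(tight_pbs) <= len(loose)
        assert len(tight_xp) <= len(loose)

    def test_index_snp_is_regional_pbs_maximum(self):
        vals, at = _spiked()
        vals[at + 3] = 9.0
        scan = _scan_with_windows(vals)
        std = np.full(len(vals), 3.0)
        regions = call_candidates(scan, _xpehh(len(vals), std), 99.0, 2.0)
        for r in regions:
            members = np.arange(r.start_idx, r.end_idx + 1)
            assert scan.values[r.index_idx] == np.nanmax(scan.values[members])


class TestAttachPvalues:
    def _one_region(self):
        vals, at = _spiked()
        scan = _scan_with_windows(vals)
        std = np.zeros(len(vals))
        std[at] = 5.0
        return call_candidates(scan, _xpehh(len(vals), std), 99.0, 2.0)

    def test_region_above_null_maximum_significant(self):
        regions = attach_pvalues(self._one_region(), np.zeros(1000))
        assert regions[0].p_value == pytest.approx(1 / 1001)
        assert regions[0].significant

    def test_region_below_null_median_not_significant(self):
        null = np.linspace(1.0, 2.0, 1000)
        vals = np.zeros(2000)
        vals[1000] = 0.5  # window mean ~ 0.025, far below null
        scan = _scan_with_windows(vals)
        std = np.zeros(2000)
        std[1000] = 5.0
        regions = call_candidates(scan, _xpehh(2000, std), 99.0, 2.0)
        regions = attach_pvalues(regions, null)
        assert regions[0].p_value > 0.5 and not regions[0].significant

    def test_missing_null_is_config_error(self):
        with pytest.raises(ConfigurationError):
            attach_pvalues(self._one_region(), np.array([]))


class TestNearestGene:
    def _region(self, start, end):
        from sweepscan.regions import CandidateRegion
        return CandidateRegion(chrom="1", start_bp=start, end_bp=end,
                               start_idx=0, end_idx=0, index_idx=0,
                               index_id=".", index_pos=start, index_pbs=0.0,
                               mean_pbs=0.0, max_xpehh=0.0)

    def _genes(self):
        return GeneTable(name=np.array(["G1", "G2"], dtype=object),
                         chrom=np.array(["1", "1"], dtype=object),
                         start=np.array([1000, 4999]), end=np.array([2000, 6000]))

    def test_region_inside_gene_distance_zero(self):
        g, d = nearest_gene(self._region(1200, 1300), self._genes())
        assert g == "G1" and d == 0

    def test_gap_distance_and_tie_to_smaller_start(self):
        # 1500 bp to G1 (ends at 2000) and 1500 bp to G2 (1-based start 5000)
        g, d = nearest_gene(self._region(3500, 3500), self._genes())
        assert g == "G1" and d == 1500

    def test_matches_brute_force_over_random_genes(self, rng):
        starts = np.sort(rng.choice(np.arange(100, 100_000, 10), 30, replace=False))
        genes = GeneTable(name=np.array([f"g{i}" for i in range(30)], dtype=object),
                          chrom=np.array(["1"] * 30, dtype=object),
                          start=starts, end=starts + 500)
        for _ in range(40):
            s = int(rng.integers(1, 110_000))
            e = s + int(rng.integers(0, 2000))
            g, d = nearest_gene(self._region(s, e), genes)
            brute = min(max(gs + 1 - e, s - ge, 0)
                        for gs, ge in zip(genes.start, genes.end))
            assert d == brute

    def test_empty_gene_table_skips_annotation(self):
        regions = annotate_regions([self._region(10, 20)],
                                   GeneTable(name=np.array([], dtype=object),
                                             chrom=np.array([], dtype=object),
                                             start=np.array([], dtype=np.int64),
                                             end=np.array([], dtype=np.int64)))
        assert regions[0].nearest_gene == "" and regions[0].gene_distance == -1


def test_regions_frame_columns_match_report_schema():
    df = regions_to_frame([])
    assert list(df.columns)[:5] == ["chrom", "start_bp", "end_bp", "index_id",
                                    "index_pos"]
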