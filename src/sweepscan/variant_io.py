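"""Shared in-memory data model and readers/writers for the standard formats.

Conventions
-----------
* VCF coordinates are 1-based inclusive; BED is 0-based half-open.  All
  internal physical distances are in bp between 1-based positions.
* Only biallelic SNP records are kept; multiallelic and indel records are
  skipped (with a count), matching an array-genotype analysis.
* Missing genotypes are allowed in dosage matrices (encoded -1) but never in
  haplotype matrices: haplotypes require fully phased input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from .errors import ConfigurationError, FormatError, PhasingError

logger = logging.getLogger(__name__)

MISSING = -1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Per-site metadata shared by every scan.

    Attributes
    ----------
    chrom : array of str, chromosome label per site
    pos : int64 array, 1-based physical position
    ref, alt : arrays of allele strings
    ids : array of variant identifiers ('.' if absent)
    cm : float64 array of interpolated genetic positions (centimorgans),
        or None until :func:`interpolate_cm` is called.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ids: np.ndarray | None = None
    cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.ids is None:
            self.ids = np.asarray(["."] * len(self.pos), dtype=object)
        self.validate()

    def validate(self) -> None:
        for c in np.unique(self.chrom.astype(str)):
            sel = self.chrom.astype(str) == c
            p = self.pos[sel]
            if np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on {c}")
            if self.cm is not None and np.any(np.diff(self.cm[sel]) < 0):
                raise FormatError(f"cM positions decrease on {c}")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom.astype(str) == str(chrom))


@dataclass
class GenotypeSet:
    """Diploid dosage matrix, individuals x sites, values in {0,1,2,-1}."""

    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.samples):
            raise FormatError("dosage matrix inconsistent with sample list")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]


@dataclass
class HaplotypeSet:
    """Phased allele matrix, haplotypes x sites, values in {0,1}.

    Row 2*i and 2*i+1 are the two haplotypes of diploid individual i.
    """

    alleles: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.shape[0] != 2 * len(self.samples):
            raise FormatError("haplotype matrix must have two rows per individual")
        if self.alleles.size and self.alleles.max() > 1:
            raise FormatError("haplotype alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def individual_of(self, hap_index: int) -> str:
        return self.samples[hap_index // 2]

    def to_genotypes(self) -> GenotypeSet:
        d = self.alleles[0::2].astype(np.int8) + self.alleles[1::2].astype(np.int8)
        return GenotypeSet(d, list(self.samples))

    def subset_individuals(self, indices: np.ndarray) -> "HaplotypeSet":
        indices = np.asarray(indices, dtype=np.int64)
        rows = np.empty(2 * len(indices), dtype=np.int64)
        rows[0::2] = 2 * indices
        rows[1::2] = 2 * indices + 1
        return HaplotypeSet(self.alleles[rows], [self.samples[i] for i in indices])


@dataclass
class PopulationMap:
    """sample id -> population label, plus optional ancestry proportions."""

    assignments: dict[str, str]
    ancestry: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, vec in self.ancestry.items():
            total = sum(vec.values())
            if abs(total - 1.0) > 1e-6 or any(not 0 <= v <= 1 for v in vec.values()):
                raise ConfigurationError(
                    f"ancestry fractions for {pop} must lie in [0,1] and sum to 1"
                )

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def population_of(self, sample: str) -> str:
        return self.assignments[sample]

    def indices(self, samples: list[str], population: str) -> np.ndarray:
        """Row indices (into *samples*) of members of *population*.

        Samples absent from the map are dropped with a warning, never
        silently assigned.
        """
        missing = [s for s in samples if s not in self.assignments]
        if missing:
            logger.warning(
                "%d samples missing from population map (dropped): %s ...",
                len(missing), ", ".join(missing[:5]),
            )
        return np.asarray(
            [i for i, s in enumerate(samples)
             if self.assignments.get(s) == population],
            dtype=np.int64,
        )


@dataclass
class GeneTable:
    """BED-style gene intervals: 0-based half-open [start, end)."""

    name: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.start >= self.end):
            raise FormatError("gene intervals require start < end")

    def __len__(self) -> int:
        return len(self.start)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, require_phased: bool = False):
    """Read a VCF with GT fields into the shared data model.

    Returns ``(VariantTable, GenotypeSet, HaplotypeSet | None, samples)``.
    Non-biallelic and non-SNP records are skipped (logged count).  With
    ``require_phased`` every genotype must use the phased separator and be
    non-missing, otherwise a :class:`PhasingError` is raised.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, refs, alts, ids = [], [], [], [], []
    dos_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    n_skipped = 0
    phased_ok = True
    seen: set[tuple[str, int]] = set()
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        key = (v.CHROM, v.POS)
        if key in seen:
            raise FormatError(f"duplicate position {v.CHROM}:{v.POS}")
        seen.add(key)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        ids.append(v.ID or ".")
        gts = v.genotypes  # [allele_a, allele_b, phased] per sample
        dos = np.empty(len(samples), dtype=np.int8)
        hap = np.empty(2 * len(samples), dtype=np.int16)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                dos[i] = MISSING
                hap[2 * i] = hap[2 * i + 1] = -1
                phased_ok = False
            else:
                dos[i] = a + b
                hap[2 * i], hap[2 * i + 1] = a, b
                if not g[2]:
                    phased_ok = False
        dos_rows.append(dos)
        hap_rows.append(hap)
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP records", n_skipped)
    if not poss:
        raise FormatError(f"no biallelic SNP records in {path}")
    order = np.lexsort((np.asarray(poss), np.asarray(chroms, dtype=object).astype(str)))
    vt = VariantTable(
        chrom=np.asarray(chroms, dtype=object)[order],
        pos=np.asarray(poss, dtype=np.int64)[order],
        ref=np.asarray(refs, dtype=object)[order],
        alt=np.asarray(alts, dtype=object)[order],
        ids=np.asarray(ids, dtype=object)[order],
    )
    genos = GenotypeSet(np.stack(dos_rows, axis=1)[:, order], samples)
    haps = None
    if require_phased:
        if not phased_ok:
            raise PhasingError(f"{path}: unphased or missing genotypes present")
        haps = HaplotypeSet(
            np.stack(hap_rows, axis=1)[:, order].astype(np.uint8), samples
        )
    vt._skipped_records = n_skipped  # type: ignore[attr-defined]
    return vt, genos, haps, samples


def write_vcf(path: str, variants: VariantTable, haplotypes: HaplotypeSet | None = None,
              genotypes: GenotypeSet | None = None) -> None:
    """Write a minimal VCF 4.2 with GT-only records (phased if haplotypes given)."""
    if haplotypes is None and genotypes is None:
        raise ConfigurationError("write_vcf needs haplotypes or genotypes")
    samples = haplotypes.samples if haplotypes is not None else genotypes.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in variants.chromosomes():
            sel = variants.chrom_slice(c)
            fh.write(f"##contig=<ID={c},length={int(variants.pos[sel].max()) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(len(variants)):
            if haplotypes is not None:
                col = haplotypes.alleles[:, j]
                gt = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}"
                               for i in range(len(samples)))
            else:
                d = genotypes.dosages[:, j]
                conv = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gt = "\t".join(conv[int(x)] for x in d)
            fh.write(f"{variants.chrom[j]}\t{variants.pos[j]}\t{variants.ids[j]}\t"
                     f"{variants.ref[j]}\t{variants.alt[j]}\t.\t.\t.\tGT\t{gt}\n")


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def read_genetic_map(path: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Whitespace table 'chrom pos cM' -> {chrom: (pos array, cM array)}."""
    chroms: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"bad genetic map line: {line!r}")
            chroms.setdefault(parts[0], []).append((int(parts[1]), float(parts[2])))
    out = {}
    for c, pts in chroms.items():
        pts.sort()
        pos = np.asarray([p for p, _ in pts], dtype=np.int64)
        cm = np.asarray([g for _, g in pts], dtype=np.float64)
        out[c] = (pos, cm)
    return out


def interpolate_cm(variants: VariantTable,
                   genetic_map: dict[str, tuple[np.ndarray, np.ndarray]]) -> VariantTable:
    """Attach genetic positions by piecewise-linear interpolation.

    Between flanking map points the interpolation is linear; beyond the map
    ends the terminal segment's rate (cM/bp) is extrapolated, keeping cM
    non-decreasing for a monotone map.
    """
    cm_out = np.empty(len(variants), dtype=np.float64)
    for c in variants.chromosomes():
        if c not in genetic_map:
            raise ConfigurationError(f"chromosome {c} absent from genetic map")
        mpos, mcm = genetic_map[c]
        if len(mpos) < 2:
            raise ConfigurationError(f"genetic map for {c} needs >= 2 points")
        sel = variants.chrom_slice(c)
        p = variants.pos[sel].astype(np.float64)
        val = np.interp(p, mpos.astype(np.float64), mcm)
        left_rate = (mcm[1] - mcm[0]) / (mpos[1] - mpos[0])
        right_rate = (mcm[-1] - mcm[-2]) / (mpos[-1] - mpos[-2])
        lo = p < mpos[0]
        hi = p > mpos[-1]
        val[lo] = mcm[0] - (mpos[0] - p[lo]) * left_rate
        val[hi] = mcm[-1] + (p[hi] - mpos[-1]) * right_rate
        cm_out[sel] = val
    return VariantTable(chrom=variants.chrom, pos=variants.pos, ref=variants.ref,
                        alt=variants.alt, ids=variants.ids, cm=cm_out)


# ---------------------------------------------------------------------------
# population map / BED
# ---------------------------------------------------------------------------

def read_population_map(path: str) -> PopulationMap:
    """Two-column TSV 'sample<TAB>population'.

    Optional ancestry-proportion lines of the form
    ``##ancestry <pop> <label>=<frac> [<label>=<frac> ...]`` may precede or
    follow the assignments; fractions must sum to 1.
    """
    assignments: dict[str, str] = {}
    ancestry: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##ancestry"):
                parts = line.split()
                pop = parts[1]
                vec = {}
                for tok in parts[2:]:
                    label, frac = tok.split("=")
                    vec[label] = float(frac)
                ancestry[pop] = vec
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise FormatError(f"bad population map line: {line!r}")
            assignments[parts[0]] = parts[1]
    if not assignments:
        raise FormatError(f"empty population map: {path}")
    return PopulationMap(assignments, ancestry)


def write_population_map(path: str, popmap: PopulationMap) -> None:
    with open(path, "w") as fh:
        for pop, vec in popmap.ancestry.items():
            toks = " ".join(f"{k}={v:g}" for k, v in vec.items())
            fh.write(f"##ancestry {pop} {toks}\n")
        for s, p in popmap.assignments.items():
            fh.write(f"{s}\t{p}\n")


def read_gene_bed(path: str) -> GeneTable:
    """BED4(+) gene file; columns chrom, start, end, name[, score, strand]."""
    chrom, start, end, name, strand = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"BED4 required, got: {line!r}")
            chrom.append(parts[0])
            start.append(int(parts[1]))
            end.append(int(parts[2]))
            name.append(parts[3])
            strand.append(parts[5] if len(parts) > 5 else ".")
    return GeneTable(
        name=np.asarray(name, dtype=object),
        chrom=np.asarray(chrom, dtype=object),
        start=np.asarray(start), end=np.asarray(end),
        strand=np.asarray(strand, dtype=object),
    )
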