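"""Ground-truth-labelled synthetic genotype data for every pipeline stage.

The generator is a discrete-generation forward-time Wright-Fisher simulator
with recombination, mutation, population splits and optional positive
selection in one focal population.  It emulates the statistical structure
of an array-genotype cohort from a three-population history (focal, sister,
reference/outgroup) at a desk-scale rescaling: population sizes are divided
by a factor (default 100, Ne 3e4 -> 300 diploids) while the population-scale
parameters theta = 4*Ne*mu and rho = 4*Ne*r and the scaled split times are
preserved, so drift, LD and sweep dynamics match the full-size model.

Two deliberate emulation choices, documented in the methods note:

* The emitted marker panel emulates array genotypes, not sequence: theta is
  set so that the *common* variants (pooled minor-allele frequency >= 0.05,
  the default marker filter) reach the array-like density the windowed
  scans assume (~1 marker per 2-3 kb, i.e. 20-SNP windows spanning
  ~40-60 kb).  Restricting to common markers also makes haplotype-
  homozygosity decay recombination-dominated, as it is on real arrays;
  matching a specific chip's ascertainment spectrum remains out of scope.
* The optional sweep is a hard sweep that begins in the focal *lineage*
  before the sister split: a single-copy beneficial mutation (genic
  selection, fitness (1+s) per copy, 2*Ne*s ~ 100) arises in the ancestral
  population of the focal branch, the sister population buds off while the
  allele is still rare (~10-20%) and evolves neutrally thereafter, and
  selection continues in the focal population to the present.  This is the
  selection-relaxation scenario the selection scan is designed to detect
  (the sister group left the environment driving selection), and it is the
  only sweep geometry that produces both high focal frequency and long
  focal haplotypes within the rescaled split depths.

Relative pairs (parent-offspring, full sibs) are injected by explicit
map-driven meiosis so the kinship stage has exact pedigree truth.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .errors import ConfigurationError, ModelError
from .variant_io import (HaplotypeSet, PopulationMap, VariantTable, write_vcf,
                         write_population_map)

# Desk-scale defaults (rescale factor 100 applied to Ne = 3e4):
RESCALE = 100.0
DEFAULT_N = 300                  # rescaled diploid size per population
DEFAULT_L = 1_000_000            # chromosome length, bp
# theta per bp chosen so common variants (MAF >= 0.05) reach array-like
# marker density (~1 marker / 2-3 kb in a 300-haplotype sample)
DEFAULT_MU = 1.15e-7             # rescaled per-bp per-generation rate (theta = 1.38e-4)
DEFAULT_MAF_MIN = 0.05           # pooled-sample marker (ascertainment-like) filter
DEFAULT_REC = 1.0e-6             # rescaled Morgans/bp (rho = 1.2e-3/bp preserved)
SWEEP_S = 1.0 / 6.0              # 2*Ne*s = 100 at Ne = 300
SPLIT_SISTER = 20                # rescaled generations before present (~50 kya equiv.)
SPLIT_REFERENCE = 24             # outgroup split (~60 kya equiv.)
# Allele age: a survival-conditioned sweep behaves as if starting from
# ~1/(2s) copies; 43 generations at 2*Ne*s = 100 then leaves the allele
# rare (~0.1) at the sister split and near 0.8 in the focal sample.
SWEEP_ONSET = 43
DEFAULT_SAMPLE = 50              # diploids sampled per population
MAX_SWEEP_RETRIES = 200


@dataclass
class PopulationSpec:
    name: str
    size: int
    parent: str | None = None    # None = carries the ancestral (root) lineage
    split_gen: int = 0           # generations before present (ignored for root)
    sample_size: int = DEFAULT_SAMPLE


@dataclass
class SweepSpec:
    population: str = "focal"    # deme under selection (the root/focal lineage)
    position: int = DEFAULT_L // 2
    s: float = SWEEP_S
    onset_gen: int = SWEEP_ONSET  # generations before present the mutation arises
    # a retained run must contain an actual sweep: runs where the allele
    # merely survives at low frequency are resimulated like lost ones
    min_final_freq: float = 0.5


@dataclass
class RelativesSpec:
    relationship: str            # 'parent_offspring' | 'full_sibs' | 'half_sibs'
    count: int
    population: str | None = None


@dataclass
class SimConfig:
    populations: list[PopulationSpec]
    length: int = DEFAULT_L
    mu: float = DEFAULT_MU
    rec: float = DEFAULT_REC
    burnin_factor: int = 10
    maf_min: float = DEFAULT_MAF_MIN
    sweep: SweepSpec | None = None
    relatives: list[RelativesSpec] = field(default_factory=list)
    seed: int = 0
    rescale: float = RESCALE
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.sweep is not None and self.sweep.s < 0:
            raise ConfigurationError("selection coefficient must be >= 0")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate population names")
        roots = [p for p in self.populations if p.parent is None]
        if len(roots) != 1:
            raise ConfigurationError("exactly one root population required")
        for p in self.populations:
            if p.parent is not None and p.parent not in names:
                raise ConfigurationError(f"unknown parent {p.parent!r}")


def default_config(preset: str = "neutral", seed: int = 0, **overrides) -> SimConfig:
    """Presets 'neutral', 'sweep' and 'related' with the study-shaped defaults."""
    if preset == "related":
        cfg = SimConfig(populations=[PopulationSpec("pop1", DEFAULT_N, sample_size=30)],
                        seed=seed, preset="related",
                        relatives=[RelativesSpec("parent_offspring", 5),
                                   RelativesSpec("full_sibs", 5)])
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg
    pops = [
        PopulationSpec("focal", DEFAULT_N, None, 0),
        PopulationSpec("sister", DEFAULT_N, "focal", SPLIT_SISTER),
        PopulationSpec("reference", DEFAULT_N, "focal", SPLIT_REFERENCE),
    ]
    sweep = SweepSpec() if preset == "sweep" else None
    if preset not in ("neutral", "sweep"):
        raise ConfigurationError(f"unknown preset {preset!r}")
    cfg = SimConfig(populations=pops, sweep=sweep, seed=seed, preset=preset)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class SyntheticDataset:
    variants: VariantTable
    haplotypes: HaplotypeSet
    popmap: PopulationMap
    truth: dict


# ---------------------------------------------------------------------------
# forward Wright-Fisher core
# ---------------------------------------------------------------------------

@njit(cache=False)
def _gametes_kernel(H, pos, hap0, phase0, cx_off, cx_pos, out):  # pragma: no cover
    n_gam, n_sites = out.shape
    for g in range(n_gam):
        h = hap0[g]
        ph = phase0[g]
        ci = cx_off[g]
        b = cx_off[g + 1]
        for si in range(n_sites):
            p = pos[si]
            while ci < b and cx_pos[ci] <= p:
                ph = 1 - ph
                ci += 1
            out[g, si] = H[h + ph, si]


def _make_gametes(H: np.ndarray, pos: np.ndarray, parents: np.ndarray,
                  morgans: float, length: int, rng: np.random.Generator) -> np.ndarray:
    """One gamete per entry of *parents* (diploid row indices into H/2)."""
    n_gam = len(parents)
    out = np.empty((n_gam, H.shape[1]), dtype=np.uint8)
    n_cx = rng.poisson(morgans, size=n_gam)
    cx_off = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(n_cx, out=cx_off[1:])
    cx_pos = rng.uniform(0, length, size=int(cx_off[-1]))
    for g in range(n_gam):
        seg = np.sort(cx_pos[cx_off[g]:cx_off[g + 1]])
        cx_pos[cx_off[g]:cx_off[g + 1]] = seg
    phase0 = rng.integers(0, 2, size=n_gam).astype(np.int64)
    _gametes_kernel(H, pos.astype(np.float64), (2 * parents).astype(np.int64),
                    phase0, cx_off, cx_pos.astype(np.float64), out)
    return out


class _ForwardSimulator:
    """Internal engine; one call to run() produces one dataset attempt."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.morgans = cfg.rec * cfg.length
        self.mu_locus = cfg.mu * cfg.length
        root = next(p for p in cfg.populations if p.parent is None)
        self.root = root.name
        self.by_name = {p.name: p for p in cfg.populations}
        deepest = max((p.split_gen for p in cfg.populations if p.parent), default=0)
        self.start_gen = cfg.burnin_factor * root.size + deepest
        # state
        self.demes: dict[str, np.ndarray] = {}
        self.pos = np.empty(0, dtype=np.int64)
        self.pos_set: set[int] = set()
        self.sweep_pos: int | None = None
        self.sweep_lost = False

    # -- helpers ---------------------------------------------------------
    def _total_haps(self) -> int:
        return sum(m.shape[0] for m in self.demes.values())

    def _freq_total(self) -> np.ndarray:
        tot = np.zeros(self.pos.shape[0], dtype=np.int64)
        for m in self.demes.values():
            tot += m.sum(axis=0, dtype=np.int64)
        return tot

    def _maintain_columns(self, new_cols: dict[str, np.ndarray],
                          new_pos: np.ndarray) -> None:
        if new_pos.size:
            for name in self.demes:
                self.demes[name] = np.concatenate(
                    [self.demes[name], new_cols[name]], axis=1)
            self.pos = np.concatenate([self.pos, new_pos])
        tot = self._freq_total()
        nh = self._total_haps()
        keep = (tot > 0) & (tot < nh)
        if self.sweep_pos is not None:
            hit = self.pos == self.sweep_pos
            if (tot[hit] == 0).any():
                self.sweep_lost = True
            keep |= hit
        order = np.argsort(self.pos[keep], kind="stable")
        sel = np.flatnonzero(keep)[order]
        dropped = self.pos[~keep]
        for p in dropped:
            self.pos_set.discard(int(p))
        self.pos = self.pos[sel]
        for name in self.demes:
            self.demes[name] = np.ascontiguousarray(self.demes[name][:, sel])

    def _parents(self, name: str, source: np.ndarray, n_off: int,
                 selected: bool) -> np.ndarray:
        n_par = source.shape[0] // 2
        if not selected or self.sweep_pos is None:
            return self.rng.integers(0, n_par, size=2 * n_off)
        col = np.searchsorted(self.pos, self.sweep_pos)
        if col >= len(self.pos) or self.pos[col] != self.sweep_pos:
            self.sweep_lost = True
            return self.rng.integers(0, n_par, size=2 * n_off)
        dosage = source[0::2, col].astype(np.float64) + source[1::2, col]
        w = (1.0 + self.cfg.sweep.s) ** dosage
        w /= w.sum()
        return self.rng.choice(n_par, size=2 * n_off, p=w)

    def _step(self, gen: int) -> None:
        """Produce the adults of generation *gen* from generation gen+1."""
        cfg = self.cfg
        new: dict[str, np.ndarray] = {}
        founding = {p.name for p in cfg.populations
                    if p.parent is not None and p.split_gen == gen + 1}
        active = list(self.demes) + [n for n in founding if n not in self.demes]
        gamete_owner: list[tuple[str, int]] = []
        for name in active:
            spec = self.by_name[name]
            src_name = spec.parent if name in founding else name
            source = self.demes[src_name]
            selected = (cfg.sweep is not None and name == cfg.sweep.population
                        and not name in founding and gen < cfg.sweep.onset_gen)
            parents = self._parents(name, source, spec.size, selected)
            new[name] = _make_gametes(source, self.pos, parents, self.morgans,
                                      cfg.length, self.rng)
            gamete_owner.extend((name, i) for i in range(2 * spec.size))
        # mutations: brand-new columns, one carrier gamete each
        n_mut = self.rng.poisson(self.mu_locus * len(gamete_owner))
        new_pos: list[int] = []
        new_cols = {name: np.zeros((m.shape[0], 0), dtype=np.uint8)
                    for name, m in new.items()}
        if n_mut:
            cols = {name: np.zeros((m.shape[0], n_mut), dtype=np.uint8)
                    for name, m in new.items()}
            k = 0
            for _ in range(n_mut):
                p = int(self.rng.integers(1, cfg.length + 1))
                if p in self.pos_set:
                    continue
                g = int(self.rng.integers(len(gamete_owner)))
                name, row = gamete_owner[g]
                cols[name][row, k] = 1
                self.pos_set.add(p)
                new_pos.append(p)
                k += 1
            new_cols = {name: c[:, :k] for name, c in cols.items()}
        self.demes = new
        self._maintain_columns(new_cols, np.asarray(new_pos, dtype=np.int64))

    def _inject_sweep_allele(self) -> None:
        """Add the beneficial mutation as a new single-copy column."""
        sw = self.cfg.sweep
        p = int(sw.position)
        while p in self.pos_set:
            p += 1
        deme = self.demes[sw.population]
        carrier = int(self.rng.integers(deme.shape[0]))
        at = int(np.searchsorted(self.pos, p))
        for name, m in self.demes.items():
            col = np.zeros((m.shape[0], 1), dtype=np.uint8)
            if name == sw.population:
                col[carrier, 0] = 1
            self.demes[name] = np.concatenate([m[:, :at], col, m[:, at:]], axis=1)
        self.pos = np.insert(self.pos, at, p)
        self.pos_set.add(p)
        self.sweep_pos = p

    def run(self):
        cfg = self.cfg
        root_spec = self.by_name[self.root]
        self.demes = {self.root: np.zeros((2 * root_spec.size, 0), dtype=np.uint8)}
        onset = cfg.sweep.onset_gen if cfg.sweep is not None else -1
        if cfg.sweep is not None:
            for p in cfg.populations:
                if p.name == cfg.sweep.population and p.parent is not None \
                        and onset > p.split_gen:
                    raise ConfigurationError(
                        "sweep onset precedes the selected population's founding; "
                        "put the sweep on the root lineage instead")
        checkpoint = None
        retries = 0
        gen = self.start_gen
        while gen > 0:
            if cfg.sweep is not None and gen == onset and self.sweep_pos is None:
                checkpoint = ({k: v.copy() for k, v in self.demes.items()},
                              self.pos.copy(), set(self.pos_set))
                self._inject_sweep_allele()
            self._step(gen - 1)
            gen -= 1
            if gen == 0 and cfg.sweep is not None and not self.sweep_lost:
                deme = self.demes[cfg.sweep.population]
                col = int(np.searchsorted(self.pos, self.sweep_pos))
                established = (col < len(self.pos)
                               and self.pos[col] == self.sweep_pos
                               and deme[:, col].mean() >= cfg.sweep.min_final_freq)
                if not established:
                    self.sweep_lost = True
            if self.sweep_lost:
                if retries >= MAX_SWEEP_RETRIES:
                    raise ModelError("sweep allele lost too many times")
                retries += 1
                self.demes = {k: v.copy() for k, v in checkpoint[0].items()}
                self.pos = checkpoint[1].copy()
                self.pos_set = set(checkpoint[2])
                self.sweep_pos = None
                self.sweep_lost = False
                gen = onset
        return retries


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Run the generator and package (VariantTable, HaplotypeSet, PopulationMap).

    Deterministic under ``cfg.seed``.  If a sweep allele is lost before
    sampling the post-onset phase is re-run from a checkpoint with fresh
    randomness (bounded retries, count recorded in the truth record).
    """
    if cfg.preset == "related" or (len(cfg.populations) == 1 and cfg.relatives
                                   and cfg.preset == "custom"):
        return _related_panel(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 314159]))
    sim = _ForwardSimulator(cfg, rng)
    retries = sim.run()

    # sample individuals per population
    sample_ids: list[str] = []
    rows = []
    pop_assign: dict[str, str] = {}
    for p in cfg.populations:
        deme = sim.demes[p.name]
        n = min(p.sample_size, p.size)
        idx = rng.choice(p.size, size=n, replace=False)
        for k, i in enumerate(sorted(int(x) for x in idx)):
            sid = f"{p.name}_{k:03d}"
            sample_ids.append(sid)
            pop_assign[sid] = p.name
            rows.append(deme[2 * i])
            rows.append(deme[2 * i + 1])
    alleles = np.stack(rows, axis=0)
    # marker panel: polymorphic in the pooled sample, above the MAF floor
    tot = alleles.sum(axis=0)
    nh = alleles.shape[0]
    maf = np.minimum(tot, nh - tot) / nh
    poly = (tot > 0) & (tot < nh) & (maf >= cfg.maf_min)
    if cfg.sweep is not None and sim.sweep_pos is not None:
        poly |= (sim.pos == sim.sweep_pos) & (tot > 0) & (tot < nh)
    alleles = alleles[:, poly]
    pos = sim.pos[poly]

    cm_per_bp = cfg.rec * 100.0
    vt = VariantTable(
        chrom=np.asarray(["1"] * len(pos), dtype=object),
        pos=pos,
        ref=np.asarray(["A"] * len(pos), dtype=object),
        alt=np.asarray(["G"] * len(pos), dtype=object),
        ids=np.asarray([f"s{p}" for p in pos], dtype=object),
        cm=pos.astype(np.float64) * cm_per_bp,
    )
    haps = HaplotypeSet(alleles, sample_ids)
    popmap = PopulationMap(pop_assign)

    truth: dict = {
        "preset": cfg.preset,
        "seed": cfg.seed,
        "length": cfg.length,
        "populations": {p.name: {"size": p.size, "sample_size": min(p.sample_size, p.size),
                                 "split_gen": p.split_gen} for p in cfg.populations},
        "relatives": [],
    }
    if cfg.sweep is not None:
        col = int(np.searchsorted(pos, sim.sweep_pos))
        freqs = {}
        for p in cfg.populations:
            sel = popmap.indices(sample_ids, p.name)
            sub = haps.subset_individuals(sel)
            freqs[p.name] = float(sub.alleles[:, col].mean())
        truth["sweep"] = {
            "population": cfg.sweep.population,
            "position": int(sim.sweep_pos),
            "site_index": col,
            "s": cfg.sweep.s,
            "onset_gen": cfg.sweep.onset_gen,
            "origin": "de_novo",
            "retries": retries,
            "sample_freq": freqs,
        }
    ds = SyntheticDataset(vt, haps, popmap, truth)
    if cfg.relatives:
        ds = inject_relatives(ds, cfg.relatives, seed=cfg.seed + 1)
    return ds


# ---------------------------------------------------------------------------
# frequency-level admixture panel (for the f3 test)
# ---------------------------------------------------------------------------

def simulate_admixture_panel(n_snps: int = 50_000, fst: float = 0.1,
                             alpha: float = 0.5, n_hap: int = 100,
                             spacing_bp: int = 2_500, seed: int = 0):
    """Unlinked allele-frequency panel with a known admixture event.

    Two source populations drift from a shared ancestor to pairwise
    differentiation ~``fst`` (Balding-Nichols model); the 'target' is an
    alpha/(1-alpha) frequency mixture of the sources, while the 'control'
    drifts independently from the ancestor.  Sample frequencies add
    binomial noise at ``n_hap`` haploid draws per population.  Returns
    ``(VariantTable, {population: FreqTable})``; positions are spread at
    ``spacing_bp`` so physical jackknife blocks behave like real data.
    """
    from .allele_stats import FreqTable

    rng = np.random.default_rng(np.random.SeedSequence([seed, 424242]))
    anc = rng.uniform(0.05, 0.95, size=n_snps)

    def drift(p, f):
        a = p * (1 - f) / f
        b = (1 - p) * (1 - f) / f
        return rng.beta(a, b)

    # with independent Balding-Nichols branches of parameter F, pairwise
    # Hudson FST equals F (numerator 2*F*E[pq] over denominator 2*E[pq])
    f_branch = fst
    p1 = drift(anc, f_branch)
    p2 = drift(anc, f_branch)
    p_target = alpha * p1 + (1 - alpha) * p2
    p_control = drift(anc, f_branch)

    pops = {"src1": p1, "src2": p2, "target": p_target, "control": p_control}
    n = np.full(n_snps, n_hap, dtype=np.int64)
    freqs = {name: FreqTable(name, rng.binomial(n_hap, p) / n_hap, n)
             for name, p in pops.items()}
    pos = (np.arange(n_snps, dtype=np.int64) + 1) * spacing_bp
    vt = VariantTable(
        chrom=np.asarray(["1"] * n_snps, dtype=object), pos=pos,
        ref=np.asarray(["A"] * n_snps, dtype=object),
        alt=np.asarray(["G"] * n_snps, dtype=object),
    )
    return vt, freqs


# ---------------------------------------------------------------------------
# unlinked panel + relatives ("related" preset)
# ---------------------------------------------------------------------------

def _related_panel(cfg: SimConfig) -> SyntheticDataset:
    """Unlinked HWE marker panel; LD-free, for kinship/inbreeding testing."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 271828]))
    n_snps = 10_000
    pop = cfg.populations[0]
    n_ind = pop.sample_size
    freqs = rng.uniform(0.1, 0.9, size=n_snps)
    alleles = (rng.random((2 * n_ind, n_snps)) < freqs[None, :]).astype(np.uint8)
    pos = (np.arange(n_snps, dtype=np.int64) + 1) * 10_000
    vt = VariantTable(
        chrom=np.asarray(["1"] * n_snps, dtype=object),
        pos=pos,
        ref=np.asarray(["A"] * n_snps, dtype=object),
        alt=np.asarray(["G"] * n_snps, dtype=object),
        ids=np.asarray([f"s{p}" for p in pos], dtype=object),
        cm=np.arange(n_snps, dtype=np.float64) * 500.0,  # ~free recombination
    )
    ids = [f"{pop.name}_{k:03d}" for k in range(n_ind)]
    ds = SyntheticDataset(vt, HaplotypeSet(alleles, ids),
                          PopulationMap({s: pop.name for s in ids}),
                          {"preset": "related", "seed": cfg.seed, "relatives": []})
    return inject_relatives(ds, cfg.relatives, seed=cfg.seed + 1)


def _meiosis(haps: HaplotypeSet, vt: VariantTable, individual: int,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete by crossover at map-distance-driven Poisson count."""
    cm = vt.cm
    if cm is None:
        raise ConfigurationError("meiosis needs genetic positions (cM)")
    total_m = float(cm[-1] - cm[0]) / 100.0
    n_cx = rng.poisson(total_m)
    cx = np.sort(rng.uniform(cm[0], cm[-1], size=n_cx))
    phase = (np.searchsorted(cx, cm, side="right") + rng.integers(0, 2)) % 2
    h0 = haps.alleles[2 * individual]
    h1 = haps.alleles[2 * individual + 1]
    return np.where(phase == 0, h0, h1).astype(np.uint8)


def inject_relatives(ds: SyntheticDataset, specs: list[RelativesSpec],
                     seed: int = 0) -> SyntheticDataset:
    """Append pedigree offspring to a dataset; truth lists (pair, expected Phi).

    Parents are consumed from the existing (assumed unrelated) samples of
    the target population, two per family, never reused across families.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99991]))
    samples = list(ds.haplotypes.samples)
    rows = [ds.haplotypes.alleles]
    assignments = dict(ds.popmap.assignments)
    truth_pairs = list(ds.truth.get("relatives", []))
    used: set[str] = set()
    fam = 0
    for spec in specs:
        pop = spec.population or assignments[samples[0]]
        pool = [s for s in samples if assignments[s] == pop and s not in used]
        if spec.relationship not in ("parent_offspring", "full_sibs", "half_sibs"):
            raise ConfigurationError(f"unknown relationship {spec.relationship!r}")
        n_parents = 3 if spec.relationship == "half_sibs" else 2
        for _ in range(spec.count):
            if len(pool) < n_parents:
                raise ConfigurationError("not enough unrelated parents available")
            parents = [pool.pop(0) for _ in range(n_parents)]
            used.update(parents)
            pidx = [samples.index(p) for p in parents]
            if spec.relationship == "parent_offspring":
                matings = [(0, 1)]
            elif spec.relationship == "full_sibs":
                matings = [(0, 1), (0, 1)]
            else:  # half sibs: shared parent 0
                matings = [(0, 1), (0, 2)]
            children = []
            for c, (mi, fi) in enumerate(matings):
                child = f"fam{fam}_{spec.relationship}_{c}"
                g1 = _meiosis(ds.haplotypes, ds.variants, pidx[mi], rng)
                g2 = _meiosis(ds.haplotypes, ds.variants, pidx[fi], rng)
                rows.append(np.stack([g1, g2]))
                samples.append(child)
                assignments[child] = pop
                children.append(child)
                for pi in (mi, fi):
                    truth_pairs.append({"pair": [parents[pi], child], "relationship":
                                        "parent_offspring", "expected_phi": 0.25})
            if spec.relationship == "full_sibs":
                truth_pairs.append({"pair": children, "relationship": "full_sibs",
                                    "expected_phi": 0.25})
            elif spec.relationship == "half_sibs":
                truth_pairs.append({"pair": children, "relationship": "half_sibs",
                                    "expected_phi": 0.125})
            fam += 1
    truth = dict(ds.truth)
    truth["relatives"] = truth_pairs
    return SyntheticDataset(ds.variants,
                            HaplotypeSet(np.concatenate(rows, axis=0), samples),
                            PopulationMap(assignments, ds.popmap.ancestry),
                            truth)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(ds: SyntheticDataset, out_dir: str) -> dict[str, str]:
    """Emit VCF + population map + genetic map + truth JSON (text only)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "fixture.vcf"),
        "popmap": os.path.join(out_dir, "populations.tsv"),
        "genetic_map": os.path.join(out_dir, "genetic.map"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_vcf(paths["vcf"], ds.variants, haplotypes=ds.haplotypes)
    write_population_map(paths["popmap"], ds.popmap)
    with open(paths["genetic_map"], "w") as fh:
        for c in ds.variants.chromosomes():
            sel = ds.variants.chrom_slice(c)
            first, last = sel[0], sel[-1]
            fh.write(f"{c} {ds.variants.pos[first]} {ds.variants.cm[first]:.8f}\n")
            fh.write(f"{c} {ds.variants.pos[last]} {ds.variants.cm[last]:.8f}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
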