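"""Pairwise kinship, inbreeding, family networks and relatedness pruning.

Kinship follows the classic genotype-array workflow: method-of-moments IBD
estimation from population allele frequencies (the PLINK ``--genome``
derivation, with finite-sample-corrected expected IBS proportions), giving
per pair the probabilities (P0, P1, P2) of sharing 0/1/2 alleles identical
by descent, PI_HAT = P2 + P1/2 and the kinship coefficient
Phi = P1/4 + P2/2.  Individual inbreeding F uses the observed-vs-expected
homozygosity moment estimator.

Family networks connect pairs with Phi at or above a threshold (default
0.1, i.e. second-degree or closer; 0.0625 would admit third-degree pairs).
Pruning iteratively removes the individual with the most relatives, which
empties the edge set with minimal sample loss on family-star structures.
Because an interactive procedure is not reproducible, ties are broken
deterministically: larger summed incident Phi first, then smallest id.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .allele_stats import FreqTable
from .errors import ConfigurationError, EstimationError
from .variant_io import MISSING, GenotypeSet

DEFAULT_PHI_THRESHOLD = 0.1
DEFAULT_MIN_SITES = 10_000
PI_HAT_DISPLAY = 0.05


def _expected_ibs_terms(freqs: FreqTable, site_mask: np.ndarray):
    """Per-site expected IBS proportions given IBD state, bias-corrected.

    Uses unbiased estimators of the allele-frequency monomials (products of
    falling factorials of the allele counts), so that e.g. E[2 p^2 q^2] is
    estimated without the upward bias of plugging in sample frequencies.
    """
    m = freqs.n[site_mask].astype(np.float64)
    a = np.round(freqs.p[site_mask] * m)
    b = m - a

    def ff(x, k):
        out = np.ones_like(x)
        for i in range(k):
            out = out * (x - i)
        return out

    m4 = ff(m, 4)
    m3 = ff(m, 3)
    u_p2q2 = ff(a, 2) * ff(b, 2) / m4
    u_p3q = ff(a, 3) * b / m4
    u_pq3 = a * ff(b, 3) / m4
    u_p4 = ff(a, 4) / m4
    u_q4 = ff(b, 4) / m4
    u_p2q = ff(a, 2) * b / m3
    u_pq2 = a * ff(b, 2) / m3

    e00 = 2.0 * u_p2q2
    e10 = 4.0 * u_p3q + 4.0 * u_pq3
    e20 = u_p4 + u_q4 + 4.0 * u_p2q2
    e11 = 2.0 * u_p2q + 2.0 * u_pq2
    e21 = 1.0 - e11
    return e00, e10, e20, e11, e21


def _usable_sites(freqs: FreqTable) -> np.ndarray:
    # informative sites: polymorphic with at least 4 observed alleles (the
    # quartic unbiased products need m >= 4)
    return (freqs.n >= 4) & (freqs.p > 0) & (freqs.p < 1)


def ibd_probabilities(genos: GenotypeSet, freqs: FreqTable, pair: tuple[int, int],
                      min_sites: int = DEFAULT_MIN_SITES):
    """Method-of-moments (P0, P1, P2) for one pair of individual indices.

    Sites with a missing genotype in either member are excluded pairwise;
    estimates are truncated to [0, 1] and renormalized.  Raises
    :class:`EstimationError` when fewer than ``min_sites`` informative
    pairwise-complete sites remain (monomorphic-only input included).
    """
    i, j = pair
    d1 = genos.dosages[i]
    d2 = genos.dosages[j]
    mask = _usable_sites(freqs) & (d1 != MISSING) & (d2 != MISSING)
    if mask.sum() < min_sites:
        raise EstimationError(
            f"only {int(mask.sum())} informative sites for pair {pair}; "
            f"need >= {min_sites}")
    e00, e10, e20, e11, e21 = _expected_ibs_terms(freqs, mask)
    ibs = 2 - np.abs(d1[mask].astype(np.int16) - d2[mask].astype(np.int16))
    s0 = float(np.sum(ibs == 0))
    s1 = float(np.sum(ibs == 1))
    s2 = float(np.sum(ibs == 2))
    n = float(mask.sum())

    p0 = s0 / e00.sum()
    p1 = (s1 - p0 * e10.sum()) / e11.sum()
    p2 = (s2 - p0 * e20.sum() - p1 * e21.sum()) / n
    probs = np.clip([p0, p1, p2], 0.0, 1.0)
    total = probs.sum()
    if total == 0:
        raise EstimationError("degenerate IBD estimate")
    probs = probs / total
    return float(probs[0]), float(probs[1]), float(probs[2])


def inbreeding_f(genos: GenotypeSet, freqs: FreqTable, individual: int) -> float:
    """F = (observed hom - expected hom) / (L - expected hom); may be < 0."""
    d = genos.dosages[individual]
    mask = _usable_sites(freqs) & (d != MISSING)
    if not mask.any():
        raise EstimationError("no informative sites for inbreeding estimate")
    p = freqs.p[mask]
    m = freqs.n[mask].astype(np.float64)
    e_het = 2.0 * p * (1.0 - p) * m / (m - 1.0)
    e_hom = float(np.sum(1.0 - e_het))
    o_hom = float(np.sum(d[mask] != 1))
    l_eff = float(mask.sum())
    if abs(l_eff - e_hom) < 1e-9:
        raise EstimationError("L equals expected homozygosity; F undefined")
    return (o_hom - e_hom) / (l_eff - e_hom)


@dataclass
class KinshipTable:
    """Pairwise IBD table plus per-individual inbreeding."""

    pairs: pd.DataFrame        # id1, id2, P0, P1, P2, PI_HAT, phi
    inbreeding: pd.DataFrame   # id, F

    def display_pairs(self, pi_hat_min: float = PI_HAT_DISPLAY) -> pd.DataFrame:
        """Pairs retained for network displays/outputs (PI_HAT filter)."""
        return self.pairs[self.pairs["PI_HAT"] > pi_hat_min]


def estimate_kinship(genos: GenotypeSet, freqs: FreqTable,
                     individuals: np.ndarray | None = None,
                     min_sites: int = DEFAULT_MIN_SITES) -> KinshipTable:
    """All-pairs kinship and all-individuals inbreeding for one sample set.

    ``freqs`` should come from the same population subset being tested:
    pooled-panel frequencies inflate apparent relatedness when the panel is
    structured.
    """
    if individuals is None:
        individuals = np.arange(genos.n_individuals)
    individuals = np.asarray(individuals, dtype=np.int64)
    rows = []
    for ai in range(len(individuals)):
        for bi in range(ai + 1, len(individuals)):
            i, j = int(individuals[ai]), int(individuals[bi])
            p0, p1, p2 = ibd_probabilities(genos, freqs, (i, j), min_sites)
            rows.append({
                "id1": genos.samples[i], "id2": genos.samples[j],
                "P0": p0, "P1": p1, "P2": p2,
                "PI_HAT": p2 + p1 / 2.0,
                "phi": p1 / 4.0 + p2 / 2.0,
            })
    fr = [{"id": genos.samples[int(i)], "F": inbreeding_f(genos, freqs, int(i))}
          for i in individuals]
    return KinshipTable(pd.DataFrame(rows), pd.DataFrame(fr))


def build_family_network(kin: KinshipTable, threshold: float = DEFAULT_PHI_THRESHOLD) -> nx.Graph:
    """Undirected graph with an edge wherever Phi >= threshold."""
    if not 0 < threshold <= 0.5:
        raise ConfigurationError("phi threshold must be in (0, 0.5]")
    g = nx.Graph()
    g.add_nodes_from(pd.concat([kin.pairs["id1"], kin.pairs["id2"]]).unique())
    for _, row in kin.pairs.iterrows():
        if row["phi"] >= threshold and row["id1"] != row["id2"]:
            g.add_edge(row["id1"], row["id2"], phi=float(row["phi"]))
    return g


def prune_related(net: nx.Graph) -> list[str]:
    """Removal order that empties the edge set.

    Repeatedly removes the node of maximum current degree; ties are broken
    by larger summed incident Phi, then by lexicographically smallest id.
    """
    g = net.copy()
    removed: list[str] = []
    while g.number_of_edges() > 0:
        best = None
        for node in g.nodes:
            deg = g.degree(node)
            if deg == 0:
                continue
            phi_sum = sum(d.get("phi", 0.0) for _, _, d in g.edges(node, data=True))
            key = (-deg, -phi_sum, str(node))
            if best is None or key < best[0]:
                best = (key, node)
        removed.append(best[1])
        g.remove_node(best[1])
    return removed
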