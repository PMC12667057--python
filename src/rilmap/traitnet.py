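"""Trait-locus network: linkage disequilibrium, locus weights and the
network-connectivity statistic.

Inbred lines are treated as haplotypes: heterozygous or missing calls are
excluded when estimating two-locus haplotype frequencies, from which D,
D' = |D| / D_max and r^2 follow in closed form.  Each locus carries, per
trait, an integer weight P(i, A) = round(-log10 p) of its association
p-value.  For a trait pair (A, B), C(A, B) is the set of loci of A that are
either shared with B or in strong LD (D' above a threshold, 0.8 by default)
with some locus of B, and the network connectivity is the geometric mean of
the weight fractions carried by the two shared-signal sets:

    NC(A, B) = sqrt( (sum_{i in C(A,B)} P(i,A) / sum_{i in L(A)} P(i,A))
                   x (sum_{i in C(B,A)} P(i,B) / sum_{i in L(B)} P(i,B)) )

The assembled graph has trait nodes (with a category attribute), locus
nodes sized by their best -log10 p across traits, association edges and
D'-qualified LD edges annotated with r^2; it is exported as GraphML and as
edge-list tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HaplotypeFreqTable:
    """Two-locus haplotype frequencies from homozygous inbred lines.

    Allele "1" at a locus is the B-parent allele (dosage 2); allele "0" is
    the A-parent allele (dosage 0).  ``p_ab[i][j]`` is the frequency of the
    haplotype with allele ``i`` at locus 1 and ``j`` at locus 2; ``p1`` and
    ``p2`` are the allele-1 margins.
    """

    p11: float
    p10: float
    p01: float
    p00: float
    n_lines: int

    @property
    def p1(self) -> float:
        return self.p11 + self.p10

    @property
    def p2(self) -> float:
        return self.p11 + self.p01


def haplotype_freqs(x1: np.ndarray, x2: np.ndarray) -> HaplotypeFreqTable:
    """Joint haplotype frequencies for two dosage vectors over lines.

    Lines heterozygous (dosage 1) or missing at either locus are excluded;
    the remaining homozygous lines are counted directly as haplotypes.
    Raises if fewer than two usable lines remain or either locus is
    monomorphic after exclusion.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("dosage vectors must be aligned over lines")
    ok = np.isin(x1, (0.0, 2.0)) & np.isin(x2, (0.0, 2.0))
    a = (x1[ok] == 2.0).astype(int)
    b = (x2[ok] == 2.0).astype(int)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("fewer than 2 usable homozygous lines")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("locus monomorphic after exclusion")
    return HaplotypeFreqTable(
        p11=float(np.mean((a == 1) & (b == 1))),
        p10=float(np.mean((a == 1) & (b == 0))),
        p01=float(np.mean((a == 0) & (b == 1))),
        p00=float(np.mean((a == 0) & (b == 0))),
        n_lines=n,
    )


@dataclass(frozen=True)
class LDEdge:
    """Pairwise linkage disequilibrium: D, D' and r^2."""

    D: float
    d_prime: float
    r2: float


def ld_stats(freqs: HaplotypeFreqTable) -> LDEdge:
    """Closed-form LD statistics from a 2x2 haplotype table.

    D = p11 - p1 p2; D' = |D| / D_max with D_max = min(p1(1-p2), (1-p1)p2)
    for D > 0 and min(p1 p2, (1-p1)(1-p2)) for D < 0; D = 0 gives D' = 0 by
    convention.  r^2 = D^2 / (p1(1-p1) p2(1-p2)).
    """
    pa, pb = freqs.p1, freqs.p2
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("degenerate margins")
    D = freqs.p11 - pa * pb
    if D > 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
    elif D < 0:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        d_max = 1.0  # D = 0 -> D' = 0
    d_prime = abs(D) / d_max
    r2 = D * D / (pa * (1 - pa) * pb * (1 - pb))
    return LDEdge(D=float(D), d_prime=float(d_prime), r2=float(r2))


def locus_weight(p: float) -> int:
    """Integer locus weight: half-up rounding of -log10(p)."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    return int(math.floor(-math.log10(p) + 0.5))


@dataclass
class TraitProfile:
    """A trait's locus set with integer association weights."""

    trait: str
    weights: dict[str, int] = field(default_factory=dict)  # locus -> P(i, trait)

    @property
    def loci(self) -> set[str]:
        return set(self.weights)

    def total_weight(self) -> int:
        return sum(self.weights.values())


@dataclass(frozen=True)
class ConnectivityResult:
    """NC(A, B) and the two shared-signal locus sets."""

    trait_a: str
    trait_b: str
    shared_ab: frozenset[str]
    shared_ba: frozenset[str]
    nc: float


def _shared_set(
    own: TraitProfile,
    other: TraitProfile,
    ld: dict[frozenset[str], float],
    threshold: float,
) -> frozenset[str]:
    out = set()
    for i in own.loci:
        if i in other.loci:
            out.add(i)
            continue
        for j in other.loci:
            if ld.get(frozenset((i, j)), 0.0) > threshold:
                out.add(i)
                break
    return frozenset(out)


def network_connectivity(
    profile_a: TraitProfile,
    profile_b: TraitProfile,
    ld_dprime: dict[frozenset[str], float] | None = None,
    d_prime_threshold: float = 0.8,
) -> ConnectivityResult:
    """Network connectivity between two traits.

    ``ld_dprime`` maps unordered locus pairs to D'; pairs absent from the
    map are treated as unlinked.  A locus of A enters C(A, B) if it is also
    a locus of B or has D' strictly above the threshold with some locus of
    B; NC is the geometric mean of the two shared-weight fractions.
    """
    ld = ld_dprime or {}
    if profile_a.total_weight() <= 0 or profile_b.total_weight() <= 0:
        raise ValueError("zero total weight for a trait profile")
    shared_ab = _shared_set(profile_a, profile_b, ld, d_prime_threshold)
    shared_ba = _shared_set(profile_b, profile_a, ld, d_prime_threshold)
    frac_a = sum(profile_a.weights[i] for i in shared_ab) / profile_a.total_weight()
    frac_b = sum(profile_b.weights[i] for i in shared_ba) / profile_b.total_weight()
    return ConnectivityResult(
        trait_a=profile_a.trait,
        trait_b=profile_b.trait,
        shared_ab=shared_ab,
        shared_ba=shared_ba,
        nc=float(np.sqrt(frac_a * frac_b)),
    )


def ld_between_loci(
    locus_dosages: dict[str, np.ndarray],
) -> tuple[dict[frozenset[str], float], pd.DataFrame]:
    """All-pairs LD between loci from their lead-bin dosage vectors.

    Pairs where haplotype frequencies are degenerate (monomorphic after
    excluding heterozygous/missing lines) are skipped.  Returns the
    D' lookup used by :func:`network_connectivity` plus a tidy table with D,
    D' and r^2 per pair.
    """
    dprime: dict[frozenset[str], float] = {}
    rows = []
    for a, b in combinations(sorted(locus_dosages), 2):
        try:
            freqs = haplotype_freqs(locus_dosages[a], locus_dosages[b])
            edge = ld_stats(freqs)
        except ValueError:
            continue
        dprime[frozenset((a, b))] = edge.d_prime
        rows.append((a, b, edge.D, edge.d_prime, edge.r2))
    table = pd.DataFrame(rows, columns=["locus_a", "locus_b", "D", "d_prime", "r2"])
    return dprime, table


def build_trait_locus_graph(
    profiles: list[TraitProfile],
    locus_dosages: dict[str, np.ndarray],
    trait_categories: dict[str, str] | None = None,
    locus_lead_p: dict[str, dict[str, float]] | None = None,
    d_prime_threshold: float = 0.8,
    r2_class_cut: float = 0.5,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Assemble the trait-locus graph.

    Nodes: one per trait (``kind="trait"``, optional ``category``) and one
    per locus (``kind="locus"``, ``size`` = max -log10 lead p over traits).
    Edges: trait-locus association edges, and locus-locus LD edges wherever
    D' strictly exceeds the threshold (annotated with D', r^2 and an r^2
    class at ``r2_class_cut``).  Also returns the pairwise NC table over all
    trait pairs.
    """
    if not profiles or all(not p.loci for p in profiles):
        raise ValueError("need at least one trait with at least one locus")
    categories = trait_categories or {}
    lead_p = locus_lead_p or {}
    dprime, ld_table = ld_between_loci(locus_dosages)

    G = nx.Graph()
    for prof in profiles:
        G.add_node(prof.trait, kind="trait", category=categories.get(prof.trait, ""))
        for locus in sorted(prof.loci):
            if locus not in G:
                G.add_node(locus, kind="locus", size=0.0)
            p = lead_p.get(prof.trait, {}).get(locus)
            neglog = -math.log10(p) if p is not None else float(prof.weights[locus])
            G.nodes[locus]["size"] = max(G.nodes[locus]["size"], neglog)
            G.add_edge(prof.trait, locus, kind="association", weight=float(prof.weights[locus]))
    for _, row in ld_table.iterrows():
        a, b = row["locus_a"], row["locus_b"]
        if a in G and b in G and row["d_prime"] > d_prime_threshold:
            G.add_edge(
                a,
                b,
                kind="ld",
                d_prime=float(row["d_prime"]),
                r2=float(row["r2"]),
                r2_class="high" if row["r2"] > r2_class_cut else "low",
            )

    nc_rows = []
    for pa, pb in combinations(profiles, 2):
        if not pa.loci or not pb.loci:
            continue
        res = network_connectivity(pa, pb, dprime, d_prime_threshold)
        nc_rows.append((pa.trait, pb.trait, res.nc, len(res.shared_ab), len(res.shared_ba)))
    nc_table = pd.DataFrame(
        nc_rows, columns=["trait_a", "trait_b", "nc", "n_shared_ab", "n_shared_ba"]
    )
    return G, nc_table


def trait_correlation_matrix(pheno: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between traits over line means (plumbing for
    heatmap-style summaries; the long table has line/trait/replicate/value
    columns)."""
    wide = pheno.pivot_table(index="line", columns="trait", values="value")
    return wide.corr(method="pearson")


def export_graph(G: nx.Graph, graphml_path, edges_tsv_path=None, ld_tsv_path=None) -> None:
    """Write GraphML plus association and LD edge-list TSVs."""
    nx.write_graphml(G, graphml_path)
    assoc_rows, ld_rows = [], []
    for u, v, data in G.edges(data=True):
        if data.get("kind") == "association":
            trait, locus = (u, v) if G.nodes[u]["kind"] == "trait" else (v, u)
            assoc_rows.append((trait, locus, data.get("weight", "")))
        else:
            ld_rows.append((u, v, data.get("d_prime", ""), data.get("r2", ""),
                            data.get("r2_class", "")))
    if edges_tsv_path is not None:
        pd.DataFrame(assoc_rows, columns=["trait", "locus", "weight"]).to_csv(
            edges_tsv_path, sep="\t", index=False
        )
    if ld_tsv_path is not None:
        pd.DataFrame(
            ld_rows, columns=["locus_a", "locus_b", "d_prime", "r2", "r2_class"]
        ).to_csv(ld_tsv_path, sep="\t", index=False)
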