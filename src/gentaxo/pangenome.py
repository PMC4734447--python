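"""Homologue identification: all-vs-all protein similarity graph, Markov
clustering (MCL), and core / pan / exclusive / orphan partitioning.

Gene ids are prefixed with their genome id (``genome|gene``).  The
similarity graph keeps every edge with alignment e-value at or below the
cutoff, weighted ``-log10(evalue)`` (capped at 200); within-genome edges
are kept so paralogs can be detected.  MCL iterates expansion (matrix
square) and inflation (entrywise power, column renormalization) on the
column-stochastic weight matrix until convergence; clusters are the
connected components of the converged matrix support.  Genes with no
qualifying edge form singleton groups, so the groups always partition the
input gene set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .aaicalc import AaiParams, _kmer_set
from .alignkern import local_align_aa
from .seqio import Proteome

__all__ = ["SimilarityGraph", "HomologGroup", "PangenomeSummary",
           "build_graph", "mcl", "summarize", "node_id"]

WEIGHT_CAP = 200.0  # -log10(evalue) ceiling for evalue underflow


def node_id(genome_id: str, gene_id: str) -> str:
    return f"{genome_id}|{gene_id}"


@dataclass
class SimilarityGraph:
    """Undirected protein similarity graph over genome-prefixed gene ids."""

    graph: nx.Graph
    genome_of: dict[str, str]
    max_evalue: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


@dataclass
class HomologGroup:
    group_id: str
    members: list[str]                 # genome-prefixed gene ids
    per_genome_count: dict[str, int]

    def is_core(self, genome_ids: list[str]) -> bool:
        return all(self.per_genome_count.get(g, 0) >= 1 for g in genome_ids)

    def is_single_copy_core(self, genome_ids: list[str]) -> bool:
        return all(self.per_genome_count.get(g, 0) == 1 for g in genome_ids)

    @property
    def exclusive_to(self) -> str | None:
        present = [g for g, c in self.per_genome_count.items() if c > 0]
        return present[0] if len(present) == 1 else None


@dataclass(frozen=True)
class PangenomeSummary:
    n_genes: int
    n_groups: int                 # multi-gene homologous groups
    n_singletons: int
    n_core: int
    n_single_copy_core: int
    n_exclusive_genes: int        # genes in groups confined to one genome
    n_orphans: int                # singleton groups: no ortholog, no paralog
    n_exclusive_with_paralog: int


def build_graph(proteomes: list[Proteome], max_evalue: float = 1e-5,
                params: AaiParams | None = None) -> SimilarityGraph:
    """All-vs-all similarity graph at the e-value cutoff.

    Every input gene becomes a node (isolated genes cluster as
    singletons); results are independent of proteome input order because
    pairs are enumerated over sorted node ids.
    """
    if len(proteomes) < 1:
        raise ValueError("at least one proteome required")
    p = params or AaiParams(max_evalue=max_evalue)
    seqs: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    for pr in proteomes:
        for gid, seq in pr.proteins.items():
            nid = node_id(pr.genome_id, gid)
            if nid in seqs:
                raise ValueError(f"duplicate gene id {nid!r}")
            seqs[nid] = seq
            genome_of[nid] = pr.genome_id
    db_size = sum(len(s) for s in seqs.values())
    g = nx.Graph()
    nodes = sorted(seqs)
    g.add_nodes_from(nodes)
    kmers = {n: _kmer_set(seqs[n]) for n in nodes} if p.seed_prefilter else None
    for na, nb in itertools.combinations(nodes, 2):
        if kmers is not None and not (kmers[na] & kmers[nb]):
            continue
        res = local_align_aa(seqs[na], seqs[nb], p.scoring, db_size=db_size,
                             query_id=na, subject_id=nb)
        if res is None or res.evalue > p.max_evalue:
            continue
        w = min(WEIGHT_CAP, -np.log10(max(res.evalue, 1e-200)))
        g.add_edge(na, nb, weight=float(w), identity=res.identity_percent,
                   evalue=res.evalue)
    return SimilarityGraph(g, genome_of, p.max_evalue)


def _mcl_matrix(mat: np.ndarray, inflation: float, max_iter: int,
                prune: float, tol: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Run MCL iterations on a column-stochastic matrix; returns the
    converged matrix and a convergence flag."""
    m = mat.copy()
    for _ in range(max_iter):
        prev = m
        m = m @ m                       # expansion
        m = np.power(m, inflation)      # inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if m.shape == prev.shape and np.max(np.abs(m - prev)) < tol:
            return m, True
    return m, False


def mcl(sim: SimilarityGraph, inflation: float = 1.25, max_iter: int = 100,
        prune: float = 1e-5) -> list[HomologGroup]:
    """Markov clustering of the similarity graph.

    Self-loops are set to each node's maximum incident weight (standard
    regularization), the matrix is column-normalized, and expansion /
    inflation iterations run to convergence; clusters are connected
    components of the converged support.  Deterministic: nodes are sorted
    lexicographically before matrix construction.  Non-convergence after
    ``max_iter`` iterations emits a warning and interprets the current
    matrix.
    """
    import warnings

    nodes = sim.nodes
    if not nodes:
        raise ValueError("empty graph")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    mat = np.zeros((n, n))
    for a, b, data in sim.graph.edges(data=True):
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = data["weight"]
    loop = mat.max(axis=0)
    loop[loop == 0] = 1.0               # isolated nodes: unit self-loop
    mat[np.diag_indices(n)] = loop
    mat = mat / mat.sum(axis=0)

    final, converged = _mcl_matrix(mat, inflation, max_iter, prune)
    if not converged:
        warnings.warn("MCL did not converge within max_iter; "
                      "interpreting the current matrix", stacklevel=2)
    support = nx.Graph()
    support.add_nodes_from(range(n))
    for i, j in zip(*np.nonzero(final)):
        if i != j:
            support.add_edge(int(i), int(j))
    groups: list[HomologGroup] = []
    comps = sorted(nx.connected_components(support), key=lambda c: nodes[min(c)])
    for k, comp in enumerate(comps):
        members = sorted(nodes[i] for i in comp)
        counts: dict[str, int] = {}
        for mbr in members:
            gm = sim.genome_of[mbr]
            counts[gm] = counts.get(gm, 0) + 1
        groups.append(HomologGroup(f"HG{k + 1:05d}", members, counts))
    return groups


def summarize(groups: list[HomologGroup], genome_ids: list[str]) -> PangenomeSummary:
    """Pan-genome partition statistics.

    ``n_groups`` counts homologous groups with at least two members;
    singleton groups are counted separately and, being exclusive with no
    paralog, are the orphans.
    """
    n_genes = sum(len(g.members) for g in groups)
    multi = [g for g in groups if len(g.members) >= 2]
    singles = [g for g in groups if len(g.members) == 1]
    n_core = sum(1 for g in multi if g.is_core(genome_ids))
    n_scc = sum(1 for g in multi if g.is_single_copy_core(genome_ids))
    excl_genes = sum(len(g.members) for g in groups if g.exclusive_to is not None)
    orphans = len(singles)
    excl_paralog = excl_genes - orphans
    return PangenomeSummary(
        n_genes=n_genes,
        n_groups=len(multi),
        n_singletons=len(singles),
        n_core=n_core,
        n_single_copy_core=n_scc,
        n_exclusive_genes=excl_genes,
        n_orphans=orphans,
        n_exclusive_with_paralog=excl_paralog,
    )


def single_copy_core(groups: list[HomologGroup], genome_ids: list[str]) -> list[HomologGroup]:
    """Groups with exactly one member in every genome (phylogeny input)."""
    return [g for g in groups if g.is_single_copy_core(genome_ids)]
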