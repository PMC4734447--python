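"""Similarity graph construction and Markov clustering.

The MCL oracle below is an independent dense-matrix transcription of the
algorithm (plain loops, column-by-column normalization) used to verify the
implementation on small graphs.
"""

import itertools
import random

import networkx as nx
import numpy as np
import pytest

from gentaxo import pangenome, simgen
from gentaxo.pangenome import HomologGroup, SimilarityGraph


def reference_mcl(nodes, edges, inflation, max_iter=100, prune=1e-5):
    """Independent dense MCL: returns a frozenset of frozensets of nodes."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = [[0.0] * n for _ in range(n)]
    for a, b, w in edges:
        m[idx[a]][idx[b]] = w
        m[idx[b]][idx[a]] = w
    for j in range(n):
        col_max = max(m[i][j] for i in range(n))
        m[j][j] = col_max if col_max > 0 else 1.0
    for j in range(n):
        s = sum(m[i][j] for i in range(n))
        for i in range(n):
            m[i][j] /= s
    for _ in range(max_iter):
        prev = [row[:] for row in m]
        sq = [[sum(m[i][k] * m[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        m = [[sq[i][j] ** inflation for j in range(n)] for i in range(n)]
        for i in range(n):
            for j in range(n):
                if m[i][j] < prune:
                    m[i][j] = 0.0
        for j in range(n):
            s = sum(m[i][j] for i in range(n)) or 1.0
            for i in range(n):
                m[i][j] /= s
        if max(abs(m[i][j] - prev[i][j]) for i in range(n) for j in range(n)) < 1e-6:
            break
    comp = nx.Graph()
    comp.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and m[i][j] > 0:
                comp.add_edge(i, j)
    return frozenset(frozenset(nodes[i] for i in c)
                     for c in nx.connected_components(comp))


def _graph_from_edges(nodes, edges):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    genome_of = {v: v.split("|")[0] for v in nodes}
    return SimilarityGraph(g, genome_of, 1e-5)


def _clique_edges(members, w=10.0):
    return [(a, b, w) for a, b in itertools.combinations(members, 2)]


class TestMcl:
    def test_two_disjoint_cliques_two_groups(self):
        nodes = [f"G1|a{i}" for i in range(4)] + [f"G2|b{i}" for i in range(4)]
        edges = _clique_edges(nodes[:4]) + _clique_edges(nodes[4:])
        groups = pangenome.mcl(_graph_from_edges(nodes, edges))
        assert sorted(len(g.members) for g in groups) == [4, 4]

    def test_matches_independent_dense_reference(self):
        rng = random.Random(0)
        for trial in range(20):
            n = rng.randint(5, 30)
            nodes = [f"G{i % 3}|n{i:02d}" for i in range(n)]
            edges = []
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.2:
                    edges.append((a, b, rng.uniform(1.0, 50.0)))
            for inflation in (1.25, 2.0):
                groups = pangenome.mcl(_graph_from_edges(nodes, edges),
                                       inflation=inflation)
                mine = frozenset(frozenset(g.members) for g in groups)
                want = reference_mcl(nodes, edges, inflation)
                assert mine == want, f"trial {trial} inflation {inflation}"

    def test_higher_inflation_never_merges_barbell_clusters(self):
        # two 4-cliques joined by one weak bridge
        left = [f"G1|l{i}" for i in range(4)]
        right = [f"G2|r{i}" for i in range(4)]
        edges = _clique_edges(left) + _clique_edges(right) + [(left[0], right[0], 1.0)]
        nodes = left + right
        previous = None
        for inflation in (1.25, 2.0, 4.0):
            groups = pangenome.mcl(_graph_from_edges(nodes, edges), inflation=inflation)
            parts = frozenset(frozenset(g.members) for g in groups)
            if previous is not None:
                # every cluster at higher inflation fits inside one previous cluster
                for p in parts:
                    assert any(p <= q for q in previous)
            previous = parts

    def test_partition_property(self):
        rng = random.Random(1)
        nodes = [f"G{i % 2}|n{i}" for i in range(20)]
        edges = [(a, b, rng.uniform(1, 30))
                 for a, b in itertools.combinations(nodes, 2) if rng.random() < 0.15]
        groups = pangenome.mcl(_graph_from_edges(nodes, edges))
        seen = [m for g in groups for m in g.members]
        assert sorted(seen) == sorted(nodes)


@pytest.fixture(scope="module")
def family_fixture():
    return simgen.fixture_suite("ortholog_families", seed=11)


class TestBuildGraph:

    def test_planted_families_cluster_single_copy(self, family_fixture):
        prots = list(family_fixture["proteomes"].values())
        graph = pangenome.build_graph(prots)
        groups = pangenome.mcl(graph, inflation=1.25)
        genome_ids = sorted(p.genome_id for p in prots)
        assert len(groups) == 50
        assert all(g.is_single_copy_core(genome_ids) for g in groups)

    def test_graph_independent_of_input_order(self, family_fixture):
        prots = list(family_fixture["proteomes"].values())
        g1 = pangenome.build_graph(prots)
        g2 = pangenome.build_graph(prots[::-1])
        assert set(g1.graph.edges) == set(g2.graph.edges)

    def test_unrelated_random_proteins_share_no_edges(self):
        rng = random.Random(2)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        from gentaxo.seqio import Proteome
        pa = Proteome("G1", {f"p{i}": "".join(rng.choice(aas) for _ in range(120))
                             for i in range(8)})
        pb = Proteome("G2", {f"p{i}": "".join(rng.choice(aas) for _ in range(120))
                             for i in range(8)})
        graph = pangenome.build_graph([pa, pb])
        assert graph.graph.number_of_edges() == 0


class TestSummarize:
    def _group(self, gid, members):
        counts = {}
        for m in members:
            g = m.split("|")[0]
            counts[g] = counts.get(g, 0) + 1
        return HomologGroup(gid, members, counts)

    def test_single_genome_core_equals_groups(self):
        groups = [self._group("HG1", ["G1|a", "G1|b"]),
                  self._group("HG2", ["G1|c", "G1|d"]),
                  self._group("HG3", ["G1|e"])]
        s = pangenome.summarize(groups, ["G1"])
        assert s.n_core == s.n_groups == 2
        assert s.n_orphans == 1

    def test_orphans_plus_paralogs_equals_exclusive(self):
        groups = [self._group("HG1", ["G1|a", "G2|a"]),
                  self._group("HG2", ["G1|p1", "G1|p2"]),  # exclusive with paralog
                  self._group("HG3", ["G2|x"])]            # orphan
        s = pangenome.summarize(groups, ["G1", "G2"])
        assert s.n_exclusive_genes == 3
        assert s.n_orphans + s.n_exclusive_with_paralog == s.n_exclusive_genes

    def test_removing_genome_preserves_or_grows_core(self):
        groups = [self._group("HG1", ["G1|a", "G2|a", "G3|a"]),
                  self._group("HG2", ["G1|b", "G2|b"])]
        with_three = pangenome.summarize(groups, ["G1", "G2", "G3"]).n_core
        groups2 = [self._group("HG1", ["G1|a", "G2|a"]),
                   self._group("HG2", ["G1|b", "G2|b"])]
        with_two = pangenome.summarize(groups2, ["G1", "G2"]).n_core
        assert with_two >= with_three
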