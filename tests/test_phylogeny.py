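"""Progressive MSA, back-translation, Tajima-Nei, NJ and bootstrap."""

import math
import random
from fractions import Fraction

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gentaxo import phylogeny
from gentaxo.alignkern import ScoringScheme, global_align
from gentaxo.phylogeny import Clade, DistanceMatrix, Msa

AA = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=40)


def random_additive_tree(seed: int, n_taxa: int) -> Clade:
    """Random binary tree with positive branch lengths."""
    r = random.Random(seed)
    nodes = [Clade(f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 1:
        a = nodes.pop(r.randrange(len(nodes)))
        b = nodes.pop(r.randrange(len(nodes)))
        a.length = r.uniform(0.05, 1.0)
        b.length = r.uniform(0.05, 1.0)
        nodes.append(Clade(children=[a, b]))
    return nodes[0]


def tree_distance_matrix(tree: Clade, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths via dendropy (independent of nj)."""
    tns = dendropy.TaxonNamespace()
    dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                           taxon_namespace=tns)
    pdm = dt.phylogenetic_distance_matrix()
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pdm.distance(tns.get_taxon(labels[i]),
                                                 tns.get_taxon(labels[j]))
    return mat


def rf_distance(a: Clade, b: Clade) -> int:
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a.to_newick(), schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=b.to_newick(), schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestProgressiveMsa:
    def test_identical_sequences_gap_free(self):
        msa = phylogeny.progressive_msa([("a", "MKVLW"), ("b", "MKVLW"),
                                         ("c", "MKVLW")])
        assert all("-" not in r for r in msa.rows)

    def test_two_sequence_reduction_equals_pairwise(self):
        scheme = ScoringScheme("nt")
        msa = phylogeny.progressive_msa([("x", "ACGT"), ("y", "AGT")], scheme)
        res = global_align("ACGT", "AGT", scheme)
        assert msa.rows == [res.aligned_query, res.aligned_subject]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(AA, AA, AA)
    def test_ungapping_recovers_inputs(self, s1, s2, s3):
        msa = phylogeny.progressive_msa([("a", s1), ("b", s2), ("c", s3)])
        assert msa.ungapped("a") == s1
        assert msa.ungapped("b") == s2
        assert msa.ungapped("c") == s3

    def test_input_order_invariance(self):
        seqs = [("a", "MKVLWAALLG"), ("b", "MKVLWALLG"), ("c", "MKVWAALLG"),
                ("d", "MRVLWAALG")]
        m1 = phylogeny.progressive_msa(seqs)
        m2 = phylogeny.progressive_msa(seqs[::-1])
        assert m1.labels == m2.labels and m1.rows == m2.rows


class TestBacktranslate:
    def test_hand_constructed_gap(self):
        msa = phylogeny.backtranslate(Msa(["x"], ["M-K"], "aa"), {"x": "ATGAAA"})
        assert msa.rows == ["ATG---AAA"]

    def test_trailing_stop_trimmed(self):
        msa = phylogeny.backtranslate(Msa(["x"], ["MK"], "aa"), {"x": "ATGAAATAA"})
        assert msa.rows == ["ATGAAA"]

    def test_ungapping_recovers_cds(self, small_ancestor):
        prot = small_ancestor.proteome
        gids = sorted(prot.proteins)[:3]
        msa = phylogeny.progressive_msa([(g, prot.proteins[g]) for g in gids])
        nt = phylogeny.backtranslate(msa, {g: prot.cds[g] for g in gids})
        for g in gids:
            stripped = prot.cds[g]
            assert nt.ungapped(g) == stripped[: len(nt.ungapped(g))]
            assert stripped[len(nt.ungapped(g)):] in ("", "TAA", "TAG", "TGA")

    def test_length_mismatch_names_label(self):
        with pytest.raises(ValueError, match="'x'"):
            phylogeny.backtranslate(Msa(["x"], ["MKV"], "aa"), {"x": "ATGAAA"})


class TestConcatenate:
    def _msa(self, cols):
        return Msa(["a", "b"], [cols, cols], "nt")

    def test_single_alignment_identity(self):
        m = self._msa("ACGT")
        c = phylogeny.concatenate([m])
        assert c.rows == m.rows

    def test_lengths_add_and_gene_map(self):
        c = phylogeny.concatenate([self._msa("ACG"), self._msa("TTAA")])
        assert c.n_cols == 7
        assert c.gene_map == [("gene1", 0, 3), ("gene2", 3, 7)]

    def test_label_mismatch_reported(self):
        with pytest.raises(ValueError, match="label set"):
            phylogeny.concatenate([self._msa("ACG"),
                                   Msa(["a", "c"], ["ACG", "ACG"], "nt")])

    def test_gene_order_does_not_change_distances(self):
        rng = random.Random(0)
        blocks = []
        for _ in range(3):
            base = "".join(rng.choice("ACGT") for _ in range(60))
            other = "".join(c if rng.random() > 0.1 else rng.choice("ACGT")
                            for c in base)
            blocks.append(Msa(["a", "b"], [base, other], "nt"))
        d1 = phylogeny.tajima_nei(phylogeny.concatenate(blocks))
        d2 = phylogeny.tajima_nei(phylogeny.concatenate(blocks[::-1]))
        assert d1.matrix[0, 1] == pytest.approx(d2.matrix[0, 1], abs=1e-12)


def tajima_nei_scalar(row1: str, row2: str) -> float:
    """Independent exact-rational transcription of the equal-input
    correction: d = -b ln(1 - p/b), b = (1 - sum g_i^2 + p^2/h)/2,
    h = sum_{i<j} x_ij^2 / (2 g_i g_j)."""
    bases = "ACGT"
    n = len(row1)
    p = Fraction(sum(a != b for a, b in zip(row1, row2)), n)
    g = {x: Fraction(row1.count(x) + row2.count(x), 2 * n) for x in bases}
    x = {}
    for a, b in zip(row1, row2):
        if a != b:
            key = tuple(sorted((a, b)))
            x[key] = x.get(key, 0) + 1
    h = sum(Fraction(c, n) ** 2 / (2 * g[i] * g[j]) for (i, j), c in x.items())
    b_coef = (1 - sum(v**2 for v in g.values()) + p**2 / h) / 2
    return -float(b_coef) * math.log(1.0 - float(p / b_coef))


class TestTajimaNei:
    def test_identical_rows_zero(self):
        dm = phylogeny.tajima_nei(Msa(["a", "b"], ["ACGTACGT", "ACGTACGT"], "nt"))
        assert dm.matrix[0, 1] == 0.0

    def test_matches_exact_scalar_computation(self):
        row1 = "A" * 25 + "C" * 25 + "G" * 25 + "T" * 25
        r2 = list(row1)
        r2[0], r2[1], r2[25], r2[50], r2[75] = "C", "G", "G", "T", "A"
        row2 = "".join(r2)
        dm = phylogeny.tajima_nei(Msa(["a", "b"], [row1, row2], "nt"))
        assert dm.matrix[0, 1] == pytest.approx(tajima_nei_scalar(row1, row2),
                                                abs=1e-9)

    def test_column_permutation_invariance(self):
        rng = random.Random(1)
        row1 = "".join(rng.choice("ACGT") for _ in range(200))
        row2 = "".join(c if rng.random() > 0.1 else rng.choice("ACGT") for c in row1)
        perm = list(range(200))
        rng.shuffle(perm)
        d1 = phylogeny.tajima_nei(Msa(["a", "b"], [row1, row2], "nt")).matrix[0, 1]
        d2 = phylogeny.tajima_nei(Msa(["a", "b"],
                                      ["".join(row1[i] for i in perm),
                                       "".join(row2[i] for i in perm)],
                                      "nt")).matrix[0, 1]
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_correction_inflates_over_p_distance(self):
        rng = random.Random(2)
        for _ in range(10):
            row1 = "".join(rng.choice("ACGT") for _ in range(400))
            row2 = "".join(c if rng.random() > 0.15 else rng.choice("ACGT")
                           for c in row1)
            msa = Msa(["a", "b"], [row1, row2], "nt")
            tn = phylogeny.tajima_nei(msa).matrix[0, 1]
            pd = phylogeny.p_distance(msa).matrix[0, 1]
            if pd > 0:
                assert tn >= pd

    def test_saturated_pair_reported_missing_with_warning(self):
        row1 = "ACGT" * 25
        row2 = "CATG" * 25  # every site differs
        with pytest.warns(UserWarning, match="saturated"):
            dm = phylogeny.tajima_nei(Msa(["a", "b"], [row1, row2], "nt"))
        assert math.isnan(dm.matrix[0, 1])

    def test_pairwise_deletion_uses_pair_columns(self):
        # gap in row c must not affect the a-b distance
        m1 = Msa(["a", "b"], ["ACGTACGT", "ACGTACGA"], "nt")
        m2 = Msa(["a", "b", "c"], ["ACGTACGT", "ACGTACGA", "--GTACGT"], "nt")
        assert phylogeny.tajima_nei(m1).matrix[0, 1] == pytest.approx(
            phylogeny.tajima_nei(m2).matrix[0, 1])


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): d(A,B)=3, d(A,C)=5, ...
        labels = ["A", "B", "C", "D"]
        mat = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                       dtype=float)
        tree = phylogeny.nj(DistanceMatrix(labels, mat))
        assert frozenset(("A", "B")) in {frozenset(n.leaves())
                                         for n in tree.walk() if not n.is_leaf
                                         and n is not tree} | {
                                             frozenset(tree.leaves()) - frozenset(n.leaves())
                                             for n in tree.walk() if not n.is_leaf
                                             and n is not tree}
        lengths = {n.name: n.length for n in tree.walk() if n.is_leaf}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})

    def test_three_taxa_closed_form(self):
        mat = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = phylogeny.nj(DistanceMatrix(["a", "b", "c"], mat))
        lengths = {n.name: n.length for n in tree.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_recovers_random_additive_topologies(self):
        for seed in range(15):
            true = random_additive_tree(seed, 5 + seed % 6)
            labels = sorted(true.leaves())
            mat = tree_distance_matrix(true, labels)
            mine = phylogeny.nj(DistanceMatrix(labels, mat))
            assert rf_distance(true, mine) == 0

    def test_agrees_with_independent_nj_implementation(self):
        """Cross-check against scikit-bio's neighbor joining on additive
        matrices (both must recover the unique topology)."""
        import skbio

        for seed in (3, 9):
            true = random_additive_tree(seed, 7)
            labels = sorted(true.leaves())
            mat = tree_distance_matrix(true, labels)
            mine = phylogeny.nj(DistanceMatrix(labels, mat))
            ref = skbio.tree.nj(skbio.DistanceMatrix(mat, ids=labels))
            ref_clade = phylogeny.parse_newick(str(ref).strip())
            assert rf_distance(mine, ref_clade) == 0

    def test_label_permutation_isomorphic(self):
        true = random_additive_tree(5, 6)
        labels = sorted(true.leaves())
        mat = tree_distance_matrix(true, labels)
        perm = labels[::-1]
        pmat = tree_distance_matrix(true, perm)
        t1 = phylogeny.nj(DistanceMatrix(labels, mat))
        t2 = phylogeny.nj(DistanceMatrix(perm, pmat))
        assert rf_distance(t1, t2) == 0

    def test_nonfinite_distances_rejected(self):
        mat = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="non-finite"):
            phylogeny.nj(DistanceMatrix(["a", "b"], mat))


class TestNewick:
    def test_roundtrip_topology_lengths_supports(self):
        tree = random_additive_tree(11, 7)
        for node in tree.walk():
            if not node.is_leaf and node is not tree:
                node.support = 87.0
        text = tree.to_newick()
        back = parse = phylogeny.parse_newick(text)
        assert rf_distance(tree, back) == 0
        assert parse.to_newick() == text
        supports = [n.support for n in back.walk()
                    if not n.is_leaf and n is not back]
        assert all(s == 87.0 for s in supports)


@pytest.fixture(scope="module")
def alignment():
    rng = random.Random(7)
    base = "".join(rng.choice("ACGT") for _ in range(2000))

    def mutate(s, rate):
        return "".join(c if rng.random() > rate else rng.choice("ACGT")
                       for c in s)

    anc1 = mutate(base, 0.08)
    anc2 = mutate(base, 0.08)
    rows = [mutate(anc1, 0.02), mutate(anc1, 0.02),
            mutate(anc2, 0.02), mutate(anc2, 0.02)]
    return Msa(["a1", "a2", "b1", "b2"], rows, "nt")


class TestBootstrap:

    def test_same_seed_identical_supports(self, alignment):
        t1 = phylogeny.bootstrap(alignment, n_reps=25, seed=5)
        t2 = phylogeny.bootstrap(alignment, n_reps=25, seed=5)
        assert t1.to_newick() == t2.to_newick()

    def test_single_replicate_supports_binary(self, alignment):
        tree = phylogeny.bootstrap(alignment, n_reps=1, seed=6)
        sups = [n.support for n in tree.walk()
                if not n.is_leaf and n is not tree and n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_deep_split_fully_supported(self, alignment):
        tree = phylogeny.bootstrap(alignment, n_reps=50, seed=8)
        split = frozenset(("b1", "b2"))
        found = {frozenset(n.leaves()): n.support for n in tree.walk()
                 if not n.is_leaf and n is not tree}
        assert any(s == split or frozenset(alignment.labels) - s == split
                   for s in found)
        assert all(v >= 95.0 for v in found.values() if v is not None)
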