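"""Alignment kernels against an independent exhaustive-DP oracle.

The oracle is Biopython's PairwiseAligner (a full dynamic-programming
implementation wholly independent of this package's kernels), configured
with the same scoring: +1/-2 nucleotide or BLOSUM62, gap of length L
costing 11 + L.
"""

import math
import random

import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from gentaxo.alignkern import (AA_SUB, NT_SUB, ScoringScheme, global_align,
                               local_align_aa, local_align_nt, revcomp)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _nt_oracle(mode: str = "local") -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -12
    al.extend_gap_score = -1
    return al


def _aa_oracle() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -12
    al.extend_gap_score = -1
    return al


def _mutated_pair(rng: random.Random, n: int, sub_rate: float = 0.08,
                  n_indels: int = 2):
    a = "".join(rng.choice("ACGT") for _ in range(n))
    b = list(a)
    for i in range(len(b)):
        if rng.random() < sub_rate:
            b[i] = rng.choice("ACGT")
    for _ in range(n_indels):
        p = rng.randint(5, len(b) - 5)
        if rng.random() < 0.5:
            del b[p : p + rng.randint(1, 3)]
        else:
            b[p:p] = [rng.choice("ACGT") for _ in range(rng.randint(1, 3))]
    return a, "".join(b)


class TestLocalNt:
    def test_self_alignment_full_identity(self):
        q = "ACGTTGCAACGTAGCATCAATTGCA"
        r = local_align_nt(q, q)
        assert r.identity_percent == 100.0
        assert r.query_span == (0, len(q)) and r.subject_span == (0, len(q))
        assert r.strand == "+"

    def test_reverse_complement_detected_on_minus_strand(self):
        q = "ACGTTGCAACGTAGCATCAATTGCA"
        r = local_align_nt(q, revcomp(q))
        assert r.identity_percent == 100.0 and r.strand == "-"

    def test_too_short_for_seed_returns_none(self):
        assert local_align_nt("ACGT", "ACGT", k=11) is None

    def test_matches_exhaustive_dp_on_homologous_pairs(self):
        """Seed-and-extend equals full Smith-Waterman whenever a seed
        survives; never exceeds it."""
        rng = random.Random(0)
        oracle = _nt_oracle()
        mismatches = 0
        for _ in range(100):
            a, b = _mutated_pair(rng, rng.randint(50, 400))
            mine = local_align_nt(a, b)
            want = oracle.score(a, b)
            got = 0.0 if mine is None else mine.score
            assert got <= want
            if got != want:
                mismatches += 1
        assert mismatches == 0

    def test_never_exceeds_exhaustive_dp_on_random_pairs(self):
        rng = random.Random(1)
        oracle = _nt_oracle()
        for _ in range(30):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(50, 400)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(50, 400)))
            mine = local_align_nt(a, b)
            got = 0.0 if mine is None else mine.score
            assert 0.0 <= got <= oracle.score(a, b)

    def test_score_invariant_under_joint_revcomp(self):
        rng = random.Random(2)
        for _ in range(10):
            a, b = _mutated_pair(rng, 200)
            r1 = local_align_nt(a, b)
            r2 = local_align_nt(revcomp(a), revcomp(b))
            assert (r1 is None) == (r2 is None)
            if r1 is not None:
                assert r1.score == r2.score


class TestLocalAa:
    def test_identical_sequences_tiny_evalue(self):
        rng = random.Random(3)
        seq = "".join(rng.choice(AA20) for _ in range(100))
        r = local_align_aa(seq, seq, db_size=10**6)
        assert r.identity_percent == 100.0
        # Karlin-Altschul with the default gapped BLOSUM62 constants
        expected_bits = (0.267 * r.score - math.log(0.041)) / math.log(2)
        assert r.bitscore == pytest.approx(expected_bits)
        assert r.evalue == pytest.approx(100 * 10**6 * 2.0**-expected_bits)
        assert r.evalue < 1e-20

    def test_no_positive_window_returns_none(self):
        # tryptophan vs glycine runs score negatively everywhere
        assert local_align_aa("WWWW", "GGGG") is None

    def test_matches_exhaustive_dp_oracle(self):
        rng = random.Random(4)
        oracle = _aa_oracle()
        for _ in range(40):
            a = "".join(rng.choice(AA20) for _ in range(rng.randint(20, 200)))
            b = "".join(rng.choice(AA20) for _ in range(rng.randint(20, 200)))
            mine = local_align_aa(a, b)
            got = 0.0 if mine is None else mine.score
            assert got == oracle.score(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align_aa("", "MKV")


class TestGlobal:
    def test_identical(self):
        r = global_align("ACGT", "ACGT")
        assert r.identity_percent == 100.0 and r.aln_len == 4

    def test_gap_column_counts_as_nonidentity(self):
        r = global_align("ACGT", "AGT")
        assert r.aln_len == 4 and r.n_identical == 3

    def test_identity_symmetric(self):
        rng = random.Random(5)
        for _ in range(20):
            a, b = _mutated_pair(rng, 80)
            assert global_align(a, b).identity_percent == pytest.approx(
                global_align(b, a).identity_percent)

    def test_matches_exhaustive_global_oracle(self):
        rng = random.Random(6)
        oracle = _nt_oracle("global")
        for _ in range(30):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 120)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 120)))
            assert global_align(a, b).score == oracle.score(a, b)


class TestScoringScheme:
    def test_bitscore_monotone_evalue_antitone(self):
        s = NT_SUB
        bits = [s.bitscore(x) for x in (10, 20, 40)]
        assert bits == sorted(bits)
        evs = [s.evalue(x, 100, 1000) for x in (10, 20, 40)]
        assert evs == sorted(evs, reverse=True)

    def test_invalid_gap_configuration_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme("nt", gap_open=1, gap_extend=2)

    def test_default_karlin_constants_by_alphabet(self):
        assert NT_SUB.karlin_lambda == pytest.approx(1.28)
        assert AA_SUB.karlin_lambda == pytest.approx(0.267)
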