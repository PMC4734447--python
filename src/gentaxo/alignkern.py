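"""Self-contained pairwise alignment kernels with Karlin-Altschul statistics.

Three entry points cover every search need of the toolkit:

* :func:`local_align_nt` -- seed-and-extend local nucleotide alignment
  (exact k-mer seeds on both strands, diagonal chaining, windowed
  Smith-Waterman extension);
* :func:`local_align_aa` -- full Smith-Waterman protein alignment
  (proteome sizes here make the exhaustive DP affordable);
* :func:`global_align` -- Needleman-Wunsch end-to-end alignment.

Bit scores follow the Karlin-Altschul convention
``bitscore = (lambda * S - ln K) / ln 2`` and
``evalue = m * n * 2**(-bitscore)`` with m, n the query and database
lengths.  Default gapped parameters are the standard published constants
(BLOSUM62 lambda 0.267, K 0.041; +1/-2 nucleotide lambda 1.28, K 0.46);
they are configuration, not fitted values, and are recorded in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from ._kernels import nw_affine, sw_affine

__all__ = ["ScoringScheme", "AlignmentResult", "local_align_nt", "local_align_aa",
           "global_align", "revcomp", "encode_nt", "encode_aa", "NT_SUB"]

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# nucleotide encoding: A C G T -> 0..3, anything else (N/ambiguity) -> 4
_NT_IDX = np.full(128, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _NT_IDX[ord(_c)] = _i

_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_IDX = np.full(128, _AA_ORDER.index("X"), dtype=np.int8)
for _i, _c in enumerate(_AA_ORDER):
    _AA_IDX[ord(_c)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMP)[::-1]


def encode_nt(seq: str) -> np.ndarray:
    return _NT_IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return _AA_IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _nt_submatrix(match: float, mismatch: float) -> np.ndarray:
    sub = np.full((5, 5), float(mismatch))
    np.fill_diagonal(sub, float(match))
    sub[4, :] = mismatch  # N / ambiguity scores as mismatch against anything
    sub[:, 4] = mismatch
    return sub


@lru_cache(maxsize=4)
def _aa_submatrix(name: str) -> np.ndarray:
    mat = substitution_matrices.load(name)
    k = len(_AA_ORDER)
    sub = np.zeros((k, k))
    for i, a in enumerate(_AA_ORDER):
        for j, b in enumerate(_AA_ORDER):
            sub[i, j] = mat[a, b]
    return sub


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters for one alphabet.

    ``gap_open``/``gap_extend`` are positive penalties; a gap of length L
    costs ``gap_open + L * gap_extend``.
    """

    kind: str = "nt"
    match: float = 1.0
    mismatch: float = -2.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = field(default=0.0)
    karlin_k: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("nt", "aa"):
            raise ValueError(f"kind must be 'nt' or 'aa', got {self.kind!r}")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.karlin_lambda == 0.0:
            object.__setattr__(self, "karlin_lambda", 1.28 if self.kind == "nt" else 0.267)
        if self.karlin_k == 0.0:
            object.__setattr__(self, "karlin_k", 0.46 if self.kind == "nt" else 0.041)
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin parameters must be positive")

    def submatrix(self) -> np.ndarray:
        if self.kind == "nt":
            return _nt_submatrix(self.match, self.mismatch)
        return _aa_submatrix(self.matrix_name)

    def encode(self, seq: str) -> np.ndarray:
        return encode_nt(seq) if self.kind == "nt" else encode_aa(seq)

    def bitscore(self, raw: float) -> float:
        return (self.karlin_lambda * raw - math.log(self.karlin_k)) / math.log(2.0)

    def evalue(self, raw: float, m: int, n: int) -> float:
        return float(m) * float(n) * 2.0 ** (-self.bitscore(raw))


NT_SUB = ScoringScheme("nt")
AA_SUB = ScoringScheme("aa")


@dataclass
class AlignmentResult:
    """One pairwise alignment with identity, score and e-value statistics."""

    query_id: str
    subject_id: str
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_query: str
    aligned_subject: str
    n_identical: int
    aln_len: int
    score: float
    bitscore: float
    evalue: float
    strand: str = "+"

    @property
    def identity_percent(self) -> float:
        return 100.0 * self.n_identical / self.aln_len if self.aln_len else 0.0

    @property
    def query_cov(self) -> int:
        return self.query_span[1] - self.query_span[0]


def _build_alignment(q: str, s: str, qs: int, ss: int, ops: np.ndarray,
                     kind: str) -> tuple[str, str, int, int]:
    """Expand an op path into gapped strings and count identities.

    For nucleotides an N-containing column never counts as identical.
    """
    aq: list[str] = []
    asub: list[str] = []
    i, j = qs, ss
    n_id = 0
    for op in ops:
        if op == 0:
            a, b = q[i], s[j]
            aq.append(a)
            asub.append(b)
            if a == b and (kind == "aa" or a in "ACGT"):
                n_id += 1
            i += 1
            j += 1
        elif op == 1:
            aq.append(q[i])
            asub.append("-")
            i += 1
        else:
            aq.append("-")
            asub.append(s[j])
            j += 1
    return "".join(aq), "".join(asub), n_id, len(ops)


def _find_seeds(q: str, index: dict[str, list[int]], k: int) -> list[tuple[int, int]]:
    seeds = []
    for i in range(len(q) - k + 1):
        hits = index.get(q[i : i + k])
        if hits:
            for j in hits:
                seeds.append((i, j))
    return seeds


def build_kmer_index(subject: str, k: int = 11) -> dict[str, list[int]]:
    """Exact k-mer position index of a subject sequence (seeding)."""
    idx: dict[str, list[int]] = {}
    for j in range(len(subject) - k + 1):
        idx.setdefault(subject[j : j + k], []).append(j)
    return idx


def _best_diagonal_cluster(seeds: list[tuple[int, int]], k: int,
                           drift: int) -> tuple[int, int, int, int, int]:
    """Group seeds into diagonal clusters (diagonals within ``drift`` of
    each other) and return the cluster with the largest seed count:
    (dmin, dmax, qmin, qmax, n_seeds)."""
    diags = sorted(set(j - i for i, j in seeds))
    clusters: list[list[int]] = [[diags[0]]]
    for d in diags[1:]:
        if d - clusters[-1][-1] <= drift:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    best = None
    for cl in clusters:
        dset = set(cl)
        members = [(i, j) for i, j in seeds if j - i in dset]
        cand = (len(members), -min(j for _, j in members), cl, members)
        if best is None or cand[:2] > best[:2]:
            best = cand
    _, _, cl, members = best
    qmin = min(i for i, _ in members)
    qmax = max(i for i, _ in members) + k
    return cl[0], cl[-1], qmin, qmax, len(members)


def local_align_nt(query: str, subject: str, s: ScoringScheme = NT_SUB,
                   k: int = 11, query_id: str = "query", subject_id: str = "subject",
                   db_size: int | None = None, drift: int = 32,
                   subject_index: dict[str, list[int]] | None = None,
                   ) -> AlignmentResult | None:
    """Seed-and-extend local nucleotide alignment on both strands.

    Exact k-mer seeds are located on the subject (and its reverse
    complement); seeds on nearby diagonals are clustered, and the best
    cluster is extended by affine-gap Smith-Waterman restricted to a
    subject window around the cluster (the window pads the seeded
    diagonals by the query length, so the optimum is recovered whenever
    it lies near a seed).  Returns ``None`` when no seed exists on either
    strand.  Ties are broken toward the smaller subject start, then the
    plus strand.

    Precomputed indexes of the subject / reverse-complemented subject
    can be passed to amortize seeding across many queries; the minus
    strand is handled by reverse-complementing the *query* so subject
    coordinates stay on the forward strand.
    """
    if len(query) < k or len(subject) < k:
        return None
    if subject_index is None:
        subject_index = build_kmer_index(subject, k)
    sub = s.submatrix()
    es = s.encode(subject)
    m = db_size if db_size is not None else len(subject)

    # pick the strongest seed cluster across both strands, then extend it
    clusters: list[tuple] = []
    for rank, strand in enumerate(("+", "-")):
        qseq = query if strand == "+" else revcomp(query)
        seeds = _find_seeds(qseq, subject_index, k)
        if not seeds:
            continue
        dmin, dmax, qmin, qmax, n_seeds = _best_diagonal_cluster(seeds, k, drift)
        clusters.append((-n_seeds, rank, dmin, dmax, strand, qseq))
    if not clusters:
        return None
    _, _, dmin, dmax, strand, qseq = min(clusters)
    # window: the seeded diagonal band padded for full-query extension
    if len(subject) <= 4 * len(qseq):
        lo, hi = 0, len(subject)
    else:
        lo = max(0, dmin - drift - 16)
        hi = min(len(subject), len(qseq) + dmax + drift + 16)
    score, qs0, qe0, ss0, se0, ops = sw_affine(
        s.encode(qseq), es[lo:hi], sub, s.gap_open, s.gap_extend)
    if score <= 0.0:
        return None
    ss0 += lo
    se0 += lo
    aq, asub, n_id, alen = _build_alignment(qseq, subject, qs0, ss0, ops, "nt")
    qspan = (qs0, qe0) if strand == "+" else (len(query) - qe0, len(query) - qs0)
    return AlignmentResult(query_id, subject_id, qspan, (ss0, se0), aq, asub, n_id,
                           alen, score, s.bitscore(score),
                           s.evalue(score, len(query), m), strand)


def local_align_aa(query: str, subject: str, s: ScoringScheme = AA_SUB,
                   db_size: int | None = None, query_id: str = "query",
                   subject_id: str = "subject") -> AlignmentResult | None:
    """Full Smith-Waterman protein alignment with affine gaps.

    ``db_size`` is the total residue count of the searched database, used
    for the e-value; defaults to the subject length.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    if s.kind != "aa":
        s = AA_SUB
    score, qs0, qe0, ss0, se0, ops = sw_affine(
        s.encode(query), s.encode(subject), s.submatrix(), s.gap_open, s.gap_extend)
    if score <= 0.0:
        return None
    aq, asub, n_id, alen = _build_alignment(query, subject, qs0, ss0, ops, "aa")
    n = db_size if db_size is not None else len(subject)
    return AlignmentResult(query_id, subject_id, (qs0, qe0), (ss0, se0), aq, asub,
                           n_id, alen, score, s.bitscore(score),
                           s.evalue(score, len(query), n), "+")


def global_align(a: str, b: str, s: ScoringScheme = NT_SUB,
                 a_id: str = "a", b_id: str = "b") -> AlignmentResult:
    """Needleman-Wunsch end-to-end alignment.

    Identity is computed over *all* columns -- a gap column counts as a
    non-identity -- so the reported percentage is comparable across
    sequences of different length.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    score, ops = nw_affine(s.encode(a), s.encode(b), s.submatrix(),
                           s.gap_open, s.gap_extend)
    aq, asub, n_id, alen = _build_alignment(a, b, 0, 0, ops, s.kind)
    return AlignmentResult(a_id, b_id, (0, len(a)), (0, len(b)), aq, asub, n_id,
                           alen, score, s.bitscore(score),
                           s.evalue(score, len(a), len(b)), "+")
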