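"""Fragment-based Average Nucleotide Identity (ANI) between genome pairs.

The query genome is tiled into fixed-length fragments (1,020 bp by
default) and each fragment is locally aligned against the whole subject
genome on both strands.  A fragment is *retained* when its best alignment
reaches at least ``min_identity`` percent identity over at least
``min_frag_cov`` percent of the fragment length; one-way ANI is the mean
identity of retained fragments, and the two-way ANI of a pair is the
arithmetic mean of the two one-way values.  Genomes sharing no alignable
fragment yield an explicit no-signal state rather than a zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import alignkern, seqio
from .alignkern import ScoringScheme

__all__ = ["AniParams", "AniResult", "ani_oneway", "ani", "ani_matrix"]


@dataclass(frozen=True)
class AniParams:
    frag_len: int = 1020
    min_identity: float = 30.0     # percent
    min_frag_cov: float = 70.0     # percent of the fragment length
    seed_len: int = 11
    scoring: ScoringScheme = field(default_factory=lambda: ScoringScheme("nt"))


@dataclass
class OnewayAni:
    """One direction of a fragment-based ANI comparison."""

    mean_identity: float | None
    n_used: int
    n_fragments: int
    # pooled columns over retained fragments, reused by the in-silico DDH
    n_identical: int = 0
    n_columns: int = 0

    @property
    def aligned_fraction(self) -> float:
        return self.n_used / self.n_fragments if self.n_fragments else 0.0

    @property
    def no_signal(self) -> bool:
        return self.mean_identity is None


@dataclass
class AniResult:
    genome_a: str
    genome_b: str
    ani_ab: float | None
    ani_ba: float | None
    n_fragments_used_ab: int
    n_fragments_used_ba: int
    aligned_fraction_ab: float
    aligned_fraction_ba: float

    @property
    def ani(self) -> float | None:
        """Two-way ANI: arithmetic mean of the one-way means."""
        vals = [v for v in (self.ani_ab, self.ani_ba) if v is not None]
        return sum(vals) / len(vals) if vals else None

    @property
    def no_signal(self) -> bool:
        return self.ani is None


def ani_oneway(query: seqio.GenomeRecord, subject: seqio.GenomeRecord,
               params: AniParams = AniParams()) -> OnewayAni:
    """Mean identity of retained query fragments against the subject."""
    frags = seqio.fragment_genome(query, params.frag_len)
    subj_seq = subject.sequence()
    index = alignkern.build_kmer_index(subj_seq, params.seed_len)
    identities: list[float] = []
    pooled_id = pooled_cols = 0
    for frag in frags:
        res = alignkern.local_align_nt(
            frag.seq, subj_seq, params.scoring, k=params.seed_len,
            query_id=frag.fragment_id, subject_id=subject.genome_id,
            subject_index=index)
        if res is None:
            continue
        cov = 100.0 * res.query_cov / len(frag.seq)
        if res.identity_percent >= params.min_identity and cov >= params.min_frag_cov:
            identities.append(res.identity_percent)
            pooled_id += res.n_identical
            pooled_cols += res.aln_len
    if not identities:
        return OnewayAni(None, 0, len(frags))
    return OnewayAni(sum(identities) / len(identities), len(identities),
                     len(frags), pooled_id, pooled_cols)


def ani(a: seqio.GenomeRecord, b: seqio.GenomeRecord,
        params: AniParams = AniParams()) -> AniResult:
    """Two-way ANI; symmetric by construction of the two-way mean."""
    fwd = ani_oneway(a, b, params)
    rev = ani_oneway(b, a, params)
    return AniResult(a.genome_id, b.genome_id, fwd.mean_identity, rev.mean_identity,
                     fwd.n_used, rev.n_used, fwd.aligned_fraction, rev.aligned_fraction)


def ani_matrix(genomes: list[seqio.GenomeRecord],
               params: AniParams = AniParams()):
    """All-vs-all two-way ANI; returns (labels, matrix with None off-signal)."""
    labels = [g.genome_id for g in genomes]
    n = len(genomes)
    mat = [[100.0 if i == j else None for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i][j] = mat[j][i] = ani(genomes[i], genomes[j], params).ani
    return labels, mat
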