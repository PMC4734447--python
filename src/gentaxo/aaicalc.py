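"""Average Amino-acid Identity (AAI) via reciprocal best hits (RBH).

Every protein of one proteome is searched against the other by full
Smith-Waterman (an optional shared-4-mer prefilter skips pairs that share
no exact 4-mer, an approximation that cannot create hits, only skip
hopeless pairs).  A gene pair is an RBH when each is the other's highest
bit-score hit at the e-value cutoff; pairs are then filtered on identity
and on coverage of the shorter protein, and AAI is the mean identity of
the surviving pairs.  Symmetry holds by construction of the RBH set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignkern import AA_SUB, AlignmentResult, ScoringScheme, local_align_aa
from .seqio import Proteome

__all__ = ["AaiParams", "RbhPair", "AaiResult", "best_hits", "rbh_pairs", "aai"]


@dataclass(frozen=True)
class AaiParams:
    max_evalue: float = 1e-5
    min_identity: float = 30.0   # percent
    min_cov: float = 70.0        # percent of the shorter protein
    seed_prefilter: bool = True  # skip pairs sharing no exact 4-mer
    scoring: ScoringScheme = field(default_factory=lambda: ScoringScheme("aa"))


@dataclass(frozen=True)
class RbhPair:
    gene_a: str
    gene_b: str
    identity: float        # percent
    aln_len: int
    coverage_shorter: float  # percent


@dataclass
class AaiResult:
    genome_a: str
    genome_b: str
    aai: float | None
    n_rbh: int
    fraction_smaller_proteome: float
    pairs: list[RbhPair] = field(default_factory=list)

    @property
    def no_signal(self) -> bool:
        return self.aai is None


def _kmer_set(seq: str, k: int = 4) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def best_hits(pa: Proteome, pb: Proteome, max_evalue: float = 1e-5,
              params: AaiParams | None = None) -> dict[str, tuple[str, AlignmentResult]]:
    """Highest-bitscore hit in ``pb`` for every gene of ``pa``.

    Ties are broken toward the higher identity, then the lexicographically
    smaller subject gene id.  Genes without any hit are simply absent.
    """
    if not pa.proteins or not pb.proteins:
        return {}
    p = params or AaiParams(max_evalue=max_evalue)
    db_size = pb.total_residues
    kb = {g: _kmer_set(s) for g, s in pb.proteins.items()} if p.seed_prefilter else None
    out: dict[str, tuple[str, AlignmentResult]] = {}
    for ga in sorted(pa.proteins):
        sa = pa.proteins[ga]
        ka = _kmer_set(sa) if p.seed_prefilter else None
        best: tuple | None = None
        for gb in sorted(pb.proteins):
            if kb is not None and not (ka & kb[gb]):
                continue
            res = local_align_aa(sa, pb.proteins[gb], p.scoring, db_size=db_size,
                                 query_id=ga, subject_id=gb)
            if res is None or res.evalue > p.max_evalue:
                continue
            key = (-res.bitscore, -res.identity_percent, gb)
            if best is None or key < best[0]:
                best = (key, gb, res)
        if best is not None:
            out[ga] = (best[1], best[2])
    return out


def rbh_pairs(pa: Proteome, pb: Proteome, params: AaiParams = AaiParams()) -> list[RbhPair]:
    """Reciprocal best hits passing the identity and coverage filters."""
    ab = best_hits(pa, pb, params=params)
    ba = best_hits(pb, pa, params=params)
    pairs: list[RbhPair] = []
    for ga, (gb, res) in sorted(ab.items()):
        back = ba.get(gb)
        if back is None or back[0] != ga:
            continue
        shorter = min(len(pa.proteins[ga]), len(pb.proteins[gb]))
        span = min(res.query_span[1] - res.query_span[0],
                   res.subject_span[1] - res.subject_span[0])
        cov = 100.0 * span / shorter
        if res.identity_percent >= params.min_identity and cov >= params.min_cov:
            pairs.append(RbhPair(ga, gb, res.identity_percent, res.aln_len, cov))
    return pairs


def aai(pa: Proteome, pb: Proteome, params: AaiParams = AaiParams()) -> AaiResult:
    """Mean identity over filtered RBH pairs (no-signal when none survive).

    The proteome pair is canonicalized by genome id before searching, so
    ``aai(a, b)`` and ``aai(b, a)`` are bit-for-bit identical.
    """
    if not pa.proteins or not pb.proteins:
        raise ValueError("proteomes must be non-empty")
    if pa.genome_id > pb.genome_id:
        res = aai(pb, pa, params)
        return AaiResult(pa.genome_id, pb.genome_id, res.aai, res.n_rbh,
                         res.fraction_smaller_proteome,
                         [RbhPair(p.gene_b, p.gene_a, p.identity, p.aln_len,
                                  p.coverage_shorter) for p in res.pairs])
    pairs = rbh_pairs(pa, pb, params)
    smaller = min(len(pa), len(pb))
    if not pairs:
        return AaiResult(pa.genome_id, pb.genome_id, None, 0, 0.0)
    mean_id = sum(p.identity for p in pairs) / len(pairs)
    return AaiResult(pa.genome_id, pb.genome_id, mean_id, len(pairs),
                     len(pairs) / smaller, pairs)
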