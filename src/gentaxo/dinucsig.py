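"""Karlin dinucleotide relative-abundance signatures and the delta distance.

The genome signature is the vector of odds ratios
``rho*_XY = f*_XY / (f*_X * f*_Y)`` where the frequencies ``f*`` are
computed on each contig concatenated with its reverse complement (Karlin's
strand-symmetrized convention; the profile of a genome then equals the
profile of its reverse complement by construction).  Dinucleotides are
never counted across contig junctions or across the concatenation seam,
and windows containing N/ambiguity are skipped.

The distance between two genomes is the scaled L1 metric
``delta = (1/16) * sum_XY |rho*_XY(a) - rho*_XY(b)|``, reported on the raw
scale on which 0.01 is the conventional same-species ceiling; Karlin's
x1000 display convention is available as a formatting option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignkern import encode_nt, revcomp
from .seqio import GenomeRecord

__all__ = ["DinucProfile", "DeltaDistance", "dinuc_profile", "delta", "delta_matrix"]

BASES = "ACGT"
DINUCS = [a + b for a in BASES for b in BASES]


@dataclass(frozen=True)
class DinucProfile:
    genome_id: str
    rho: dict[str, float]
    n_dinucs: int

    def vector(self) -> np.ndarray:
        return np.array([self.rho[d] for d in DINUCS])


@dataclass(frozen=True)
class DeltaDistance:
    genome_a: str
    genome_b: str
    delta: float


def _count_contig(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Mono- and dinucleotide counts of one contig plus its reverse
    complement, excluding any window touching an ambiguous base."""
    mono = np.zeros(4, dtype=np.int64)
    di = np.zeros(16, dtype=np.int64)
    for s in (seq, revcomp(seq)):
        e = encode_nt(s)
        valid = e < 4
        mono += np.bincount(e[valid], minlength=5)[:4]
        if len(e) >= 2:
            ok = valid[:-1] & valid[1:]
            codes = e[:-1][ok].astype(np.int64) * 4 + e[1:][ok]
            di += np.bincount(codes, minlength=16)
    return mono, di


def dinuc_profile(g: GenomeRecord) -> DinucProfile:
    """Strand-symmetrized dinucleotide signature of a genome.

    Raises ``ValueError`` when a base letter is absent (the odds ratio is
    then undefined) or fewer than two unambiguous bases exist.
    """
    mono = np.zeros(4, dtype=np.int64)
    di = np.zeros(16, dtype=np.int64)
    for _, seq in g.contigs:
        m, d = _count_contig(seq)
        mono += m
        di += d
    if mono.sum() < 2:
        raise ValueError(f"genome {g.genome_id!r}: fewer than 2 unambiguous bases")
    if (mono == 0).any():
        missing = [BASES[i] for i in np.flatnonzero(mono == 0)]
        raise ValueError(f"genome {g.genome_id!r}: rho undefined, missing base(s) {missing}")
    f_mono = mono / mono.sum()
    n_di = int(di.sum())
    f_di = di / n_di
    rho = {}
    for i, a in enumerate(BASES):
        for j, b in enumerate(BASES):
            rho[a + b] = float(f_di[4 * i + j] / (f_mono[i] * f_mono[j]))
    return DinucProfile(g.genome_id, rho, n_di)


def delta(a: DinucProfile, b: DinucProfile) -> DeltaDistance:
    """Mean absolute signature difference over the 16 dinucleotides."""
    d = float(np.abs(a.vector() - b.vector()).mean())
    return DeltaDistance(a.genome_id, b.genome_id, d)


def delta_matrix(profiles: list[DinucProfile]) -> tuple[list[str], np.ndarray]:
    """All-vs-all delta distances; returns (labels, symmetric matrix)."""
    labels = [p.genome_id for p in profiles]
    n = len(profiles)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = delta(profiles[i], profiles[j]).delta
    return labels, mat
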