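"""FASTA I/O, genome/proteome containers, per-genome statistics and
fragmentation for fragment-based ANI.

Coordinates are 0-based half-open throughout the package.  Sequences are
stored uppercase; nucleotide records may contain IUPAC ambiguity codes,
which are kept verbatim but excluded from GC computation and treated as
mismatches by the alignment kernels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

NT_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

__all__ = [
    "GenomeRecord",
    "GenomeStats",
    "Proteome",
    "Fragment",
    "read_fasta",
    "write_fasta",
    "load_genome",
    "load_proteome",
    "genome_stats",
    "fragment_genome",
    "stats_table",
]


@dataclass
class GenomeRecord:
    """One replicon set: ordered contigs plus provenance metadata."""

    genome_id: str
    contigs: list[tuple[str, str]]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs or sum(len(s) for _, s in self.contigs) == 0:
            raise ValueError(f"genome {self.genome_id!r}: total length must be > 0")
        self.contigs = [(cid, seq.upper()) for cid, seq in self.contigs]

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def sequence(self) -> str:
        """All contigs concatenated (analysis convenience; no seam semantics)."""
        return "".join(s for _, s in self.contigs)


@dataclass(frozen=True)
class GenomeStats:
    genome_id: str
    length_bp: int
    gc_percent: float
    n_contigs: int
    n_cds: int | None = None


@dataclass
class Proteome:
    """Per-genome gene products keyed by gene id, optionally paired 1:1
    with CDS nucleotide sequences for codon back-translation.

    If ``cds`` is present, every CDS must translate to its protein (an
    optional trailing stop codon is tolerated).
    """

    genome_id: str
    proteins: dict[str, str]
    cds: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.proteins = {g: s.upper() for g, s in self.proteins.items()}
        if self.cds is not None:
            self.cds = {g: s.upper() for g, s in self.cds.items()}
            self.validate_cds()

    def validate_cds(self) -> None:
        assert self.cds is not None
        for gid, prot in self.proteins.items():
            if gid not in self.cds:
                raise ValueError(f"gene {gid!r}: protein present but CDS missing")
            nt = self.cds[gid]
            if len(nt) % 3 != 0:
                raise ValueError(f"gene {gid!r}: CDS length {len(nt)} not divisible by 3")
            aa = str(Seq(nt).translate())
            if aa.endswith("*"):
                aa = aa[:-1]
            if aa != prot:
                raise ValueError(f"gene {gid!r}: CDS translation does not match protein")

    def __len__(self) -> int:
        return len(self.proteins)

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.proteins.values())


@dataclass(frozen=True)
class Fragment:
    """A non-overlapping genome window destined for fragment-based ANI."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    seq: str

    @property
    def fragment_id(self) -> str:
        return f"{self.genome_id}:{self.contig_id}:{self.start}-{self.end}"


def read_fasta(path: str | Path | io.TextIOBase, alphabet: str = "nt") -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]``.

    Record ids are the first whitespace-delimited token of the header;
    sequences are uppercased and validated against ``alphabet`` ("nt"
    keeps IUPAC codes, "aa" allows the 20 amino acids plus X and *).

    Raises ``ValueError`` on an empty file, a duplicate id, or an
    illegal character (reported with record and position).
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    handle = path if isinstance(path, io.TextIOBase) else open(path)
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            rid = rec.id
            if rid in seen:
                raise ValueError(f"duplicate record id {rid!r}")
            seen.add(rid)
            seq = str(rec.seq).upper()
            for pos, ch in enumerate(seq):
                if ch not in allowed:
                    raise ValueError(
                        f"record {rid!r}: illegal character {ch!r} at position {pos}"
                    )
            records.append((rid, seq))
    finally:
        if not isinstance(path, io.TextIOBase):
            handle.close()
    if not records:
        raise ValueError(f"no records in {path!r}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with ``width``-column wrapping."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_genome(path: str | Path, genome_id: str | None = None,
                metadata: Mapping[str, str] | None = None) -> GenomeRecord:
    """Load a nucleotide FASTA as a single :class:`GenomeRecord`."""
    recs = read_fasta(path, "nt")
    gid = genome_id or Path(path).stem
    return GenomeRecord(gid, [(cid, seq) for cid, seq in recs], dict(metadata or {}))


def load_proteome(faa: str | Path, genome_id: str | None = None,
                  ffn: str | Path | None = None) -> Proteome:
    """Load a proteome FASTA (and optional matching CDS FASTA) for one genome."""
    gid = genome_id or Path(faa).stem
    prots = dict(read_fasta(faa, "aa"))
    cds = dict(read_fasta(ffn, "nt")) if ffn is not None else None
    return Proteome(gid, prots, cds)


def genome_stats(g: GenomeRecord, proteome: Proteome | None = None) -> GenomeStats:
    """Length, GC% and contig/CDS counts for one genome.

    GC% is ``100 * (G+C) / (A+C+G+T)`` over unambiguous bases only; a
    genome with no unambiguous base raises ``ValueError``.
    """
    gc = at = 0
    for _, seq in g.contigs:
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError(f"genome {g.genome_id!r}: no unambiguous bases")
    return GenomeStats(
        genome_id=g.genome_id,
        length_bp=g.length,
        gc_percent=100.0 * gc / (gc + at),
        n_contigs=len(g.contigs),
        n_cds=len(proteome) if proteome is not None else None,
    )


def fragment_genome(g: GenomeRecord, frag_len: int = 1020) -> list[Fragment]:
    """Cut each contig into consecutive non-overlapping ``frag_len`` windows.

    A terminal remainder is kept as a shorter fragment when it is at least
    half the window, and dropped otherwise (tiny fragments would bias the
    per-fragment identity mean).
    """
    if frag_len < 100:
        raise ValueError(f"frag_len must be >= 100, got {frag_len}")
    half = frag_len / 2
    out: list[Fragment] = []
    for cid, seq in g.contigs:
        n = len(seq)
        pos = 0
        while pos + frag_len <= n:
            out.append(Fragment(g.genome_id, cid, pos, pos + frag_len, seq[pos : pos + frag_len]))
            pos += frag_len
        if n - pos >= half and n - pos < frag_len:
            out.append(Fragment(g.genome_id, cid, pos, n, seq[pos:n]))
    return out


def stats_table(stats: Sequence[GenomeStats]) -> str:
    """Render genome statistics as TSV (GC to 2 decimals)."""
    lines = ["genome_id\tlength_bp\tgc_percent\tn_contigs\tn_cds"]
    for s in stats:
        cds = "" if s.n_cds is None else str(s.n_cds)
        lines.append(f"{s.genome_id}\t{s.length_bp}\t{s.gc_percent:.2f}\t{s.n_contigs}\t{cds}")
    return "\n".join(lines) + "\n"
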