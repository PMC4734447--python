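"""Marker-gene taxonomy: 16S rRNA identity and multi-locus sequence
analysis (MLSA) over rrsA, gyrB, pyrH, recA and rpoB.

Markers are discovered by homology to user-supplied reference sequences
(local alignment of the reference against each genome on both strands);
the best hit is extracted, reverse-complemented to reference orientation
when found on the minus strand, and rejected when covering less than half
of the reference.  Pairwise identity uses end-to-end global alignment.
MLSA aligns each marker across genomes, concatenates the alignments in a
fixed marker order with gap padding for missing markers, and reports the
p-distance matrix of the concatenation (Tajima-Nei optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import alignkern, phylogeny
from .alignkern import ScoringScheme, revcomp
from .seqio import GenomeRecord

__all__ = ["MarkerHit", "MlsaMatrix", "MLSA_MARKERS", "extract_marker",
           "marker_identity_matrix", "mlsa"]

MLSA_MARKERS = ("rrsA", "gyrB", "pyrH", "recA", "rpoB")


@dataclass
class MarkerHit:
    genome_id: str
    marker_name: str
    seq: str                      # reference-orientation extraction
    contig_id: str
    start: int                    # half-open on the source contig
    end: int
    strand: str
    identity: float               # percent identity to the reference query


@dataclass
class MlsaMatrix:
    labels: list[str]
    per_marker_identity: dict[str, phylogeny.DistanceMatrix]
    concat_alignment: phylogeny.Msa
    distances: phylogeny.DistanceMatrix
    markers_missing: dict[str, list[str]]


def extract_marker(g: GenomeRecord, ref_seq: str, name: str,
                   min_ref_cov: float = 50.0,
                   scheme: ScoringScheme | None = None) -> MarkerHit | None:
    """Best homolog of a reference marker in a genome, or None.

    The reference is aligned locally to every contig (both strands); the
    hit is discarded when the alignment covers less than ``min_ref_cov``
    percent of the reference.
    """
    if not ref_seq:
        raise ValueError("reference sequence must be non-empty")
    scheme = scheme or ScoringScheme("nt")
    best: tuple | None = None
    for cid, seq in g.contigs:
        res = alignkern.local_align_nt(ref_seq, seq, scheme, query_id=name,
                                       subject_id=cid)
        if res is None:
            continue
        key = (-res.score, res.subject_span[0], cid)
        if best is None or key < best[0]:
            best = (key, cid, seq, res)
    if best is None:
        return None
    _, cid, seq, res = best
    if 100.0 * res.query_cov / len(ref_seq) < min_ref_cov:
        return None
    start, end = res.subject_span
    extracted = seq[start:end]
    if res.strand == "-":
        extracted = revcomp(extracted)
    return MarkerHit(g.genome_id, name, extracted, cid, start, end,
                     res.strand, res.identity_percent)


def marker_identity_matrix(hits: dict[str, MarkerHit]) -> phylogeny.DistanceMatrix:
    """Pairwise global-alignment identity matrix (diagonal 100)."""
    labels = sorted(hits)
    if len(labels) < 2:
        raise ValueError("need at least 2 genomes carrying the marker")
    n = len(labels)
    mat = np.full((n, n), 100.0)
    scheme = ScoringScheme("nt")
    for i in range(n):
        for j in range(i + 1, n):
            res = alignkern.global_align(hits[labels[i]].seq, hits[labels[j]].seq,
                                         scheme)
            mat[i, j] = mat[j, i] = res.identity_percent
    return phylogeny.DistanceMatrix(labels, mat)


def mlsa(genomes: list[GenomeRecord], refs: dict[str, str],
         marker_floor: int = 3, distance: str = "p",
         markers: tuple[str, ...] = MLSA_MARKERS) -> MlsaMatrix:
    """Multi-locus sequence analysis over the configured marker set.

    Genomes carrying fewer than ``marker_floor`` markers are excluded
    (with a warning); missing markers of retained genomes are padded with
    gap columns so the concatenation stays rectangular.  ``distance`` is
    "p" (default) or "tajima_nei".
    """
    import warnings

    hits: dict[str, dict[str, MarkerHit]] = {m: {} for m in markers}
    for g in genomes:
        for m in markers:
            if m not in refs:
                continue
            h = extract_marker(g, refs[m], m)
            if h is not None:
                hits[m][g.genome_id] = h
    carried = {g.genome_id: [m for m in markers if g.genome_id in hits[m]]
               for g in genomes}
    kept = [g.genome_id for g in genomes if len(carried[g.genome_id]) >= marker_floor]
    excluded = [gid for gid in carried if gid not in kept]
    if excluded:
        warnings.warn(f"genomes below the {marker_floor}-marker floor excluded: "
                      f"{sorted(excluded)}", stacklevel=2)
    if len(kept) < 2:
        raise ValueError("fewer than 2 genomes carry enough markers")

    scheme = ScoringScheme("nt")
    per_marker_identity: dict[str, phylogeny.DistanceMatrix] = {}
    blocks: list[phylogeny.Msa] = []
    names: list[str] = []
    for m in markers:
        carriers = {gid: h for gid, h in hits[m].items() if gid in kept}
        if len(carriers) >= 2:
            per_marker_identity[m] = marker_identity_matrix(carriers)
            msa = phylogeny.progressive_msa(
                [(gid, h.seq) for gid, h in sorted(carriers.items())], scheme)
            width = msa.n_cols
            labels = list(kept)
            rows = [msa.row(gid) if gid in carriers else "-" * width
                    for gid in labels]
            blocks.append(phylogeny.Msa(labels, rows, "nt"))
            names.append(m)
    if not blocks:
        raise ValueError("no marker alignable across the retained genomes")
    concat = phylogeny.concatenate(blocks, names)
    if distance == "tajima_nei":
        dm = phylogeny.tajima_nei(concat)
    else:
        dm = phylogeny.p_distance(concat)
    missing = {gid: [m for m in markers if gid not in hits[m]]
               for gid in kept if any(gid not in hits[m] for m in markers)}
    return MlsaMatrix(list(kept), per_marker_identity, concat, dm, missing)
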