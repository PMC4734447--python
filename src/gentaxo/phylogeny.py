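"""Distance-based phylogenomic reconstruction.

The pipeline mirrors classical concatenated-gene phylogenomics: each
single-copy ortholog group is aligned at the protein level by progressive
multiple alignment, back-translated onto its source codons, the per-gene
nucleotide alignments are concatenated, pairwise distances are computed
with the Tajima-Nei (equal-input) correction, and an unrooted tree is
built by neighbor-joining; split supports come from bootstrap resampling
of alignment columns (or whole genes).

Trees are plain rooted-representation :class:`Clade` structures with an
unrooted trifurcating "root"; Newick serialization stores supports as
internal node labels and branch lengths to 6 decimals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import alignkern
from ._kernels import nw_profile
from .alignkern import ScoringScheme, encode_nt

__all__ = ["Msa", "DistanceMatrix", "Clade", "parse_newick",
           "progressive_msa", "backtranslate", "concatenate",
           "tajima_nei", "p_distance", "nj", "bootstrap"]

GAP = "-"


# ---------------------------------------------------------------------------
# containers

@dataclass
class Msa:
    """A multiple alignment: equal-length gapped rows keyed by label."""

    labels: list[str]
    rows: list[str]
    alphabet: str = "nt"
    gene_map: list[tuple[str, int, int]] | None = None  # (gene, start, end)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def ungapped(self, label: str) -> str:
        return self.row(label).replace(GAP, "")

    def codes(self) -> np.ndarray:
        """uint8 matrix: A,C,G,T -> 0..3, everything else (gap/N) -> 4."""
        return np.vstack([encode_nt(r).astype(np.uint8) for r in self.rows])


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


@dataclass
class Clade:
    """One node of a (possibly unrooted, trifurcating-root) tree."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, canonicalized to the side *not*
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaves())
        ref = min(all_leaves)
        out: set[frozenset] = set()
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaves())
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def to_newick(self, decimals: int = 6) -> str:
        return self._nwk(decimals) + ";"

    def _nwk(self, decimals: int) -> str:
        if self.is_leaf:
            body = self.name or ""
        else:
            inner = ",".join(c._nwk(decimals) for c in self.children)
            label = ""
            if self.support is not None:
                label = f"{self.support:g}"
            elif self.name:
                label = self.name
            body = f"({inner}){label}"
        if self.length is not None:
            body += f":{self.length:.{decimals}f}"
        return body


def parse_newick(text: str) -> Clade:
    """Parse a Newick string (names, branch lengths, internal labels).

    Internal labels that parse as numbers are interpreted as supports.
    """
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0

    def parse_clade() -> Clade:
        nonlocal pos
        node = Clade()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(s) and s[pos] not in ":,()":
            pos += 1
        label = s[start:pos].strip()
        if label:
            if node.children:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_clade()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick at offset {pos}")
    return root


# ---------------------------------------------------------------------------
# progressive multiple alignment

def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        out[w] = out.get(w, 0) + 1
    return out


def _kmer_cosine_dist(a: dict[str, int], b: dict[str, int]) -> float:
    if not a or not b:
        return 1.0
    dot = sum(v * b.get(w, 0) for w, v in a.items())
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    return 1.0 - dot / (na * nb) if na and nb else 1.0


def _profile_freqs(rows: list[str], scheme: ScoringScheme) -> np.ndarray:
    """Column frequency matrix (L x K); gaps carry zero weight, so
    gap-heavy columns contribute proportionally less to column scores."""
    if scheme.kind == "nt":
        idx = alignkern._NT_IDX
        k = 5
    else:
        idx = alignkern._AA_IDX
        k = len(alignkern._AA_ORDER)
    L = len(rows[0])
    freq = np.zeros((L, k))
    for r in rows:
        codes = idx[np.frombuffer(r.encode("ascii"), dtype=np.uint8)]
        gap = np.frombuffer(r.encode("ascii"), dtype=np.uint8) == ord(GAP)
        cols = np.flatnonzero(~gap)
        freq[cols, codes[cols]] += 1.0
    return freq / len(rows)


def _merge_profiles(a: tuple[list[str], list[str]], b: tuple[list[str], list[str]],
                    scheme: ScoringScheme) -> tuple[list[str], list[str]]:
    la, ra = a
    lb, rb = b
    fa = _profile_freqs(ra, scheme)
    fb = _profile_freqs(rb, scheme)
    sub = scheme.submatrix()
    scores = fa @ sub[: fa.shape[1], : fb.shape[1]] @ fb.T
    _, ops = nw_profile(scores, scheme.gap_open, scheme.gap_extend)
    new_a = ["" for _ in ra]
    new_b = ["" for _ in rb]
    ia = ib = 0
    outa: list[list[str]] = [[] for _ in ra]
    outb: list[list[str]] = [[] for _ in rb]
    for op in ops:
        if op == 0:
            for k, r in enumerate(ra):
                outa[k].append(r[ia])
            for k, r in enumerate(rb):
                outb[k].append(r[ib])
            ia += 1
            ib += 1
        elif op == 1:
            for k, r in enumerate(ra):
                outa[k].append(r[ia])
            for k in range(len(rb)):
                outb[k].append(GAP)
            ia += 1
        else:
            for k in range(len(ra)):
                outa[k].append(GAP)
            for k, r in enumerate(rb):
                outb[k].append(r[ib])
            ib += 1
    new_a = ["".join(c) for c in outa]
    new_b = ["".join(c) for c in outb]
    return la + lb, new_a + new_b


def progressive_msa(seqs: list[tuple[str, str]],
                    scheme: ScoringScheme | None = None) -> Msa:
    """Progressive multiple alignment.

    The guide tree is neighbor-joining on k-mer cosine distances (k = 3
    for proteins, 6 for nucleotides); profiles are merged leaf-to-root by
    affine-gap profile-profile global alignment scored with mean column
    substitution scores.  Ties everywhere resolve on lexicographic label
    order, so the result is independent of input order.
    """
    if not seqs:
        raise ValueError("no sequences")
    labels = [l for l, _ in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    # order-independence: canonicalize on label order
    seqs = sorted(seqs)
    if scheme is None:
        scheme = ScoringScheme("aa")
    if len(seqs) == 1:
        return Msa([seqs[0][0]], [seqs[0][1]], scheme.kind)
    if len(seqs) == 2:
        res = alignkern.global_align(seqs[0][1], seqs[1][1], scheme)
        return Msa([seqs[0][0], seqs[1][0]],
                   [res.aligned_query, res.aligned_subject], scheme.kind)

    k = 6 if scheme.kind == "nt" else 3
    counts = {l: _kmer_counts(s, k) for l, s in seqs}
    lab = [l for l, _ in seqs]
    n = len(lab)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_cosine_dist(counts[lab[i]], counts[lab[j]])
    guide = nj(DistanceMatrix(lab, dm))

    seq_of = dict(seqs)

    def align_node(node: Clade) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [seq_of[node.name]]
        parts = [align_node(c) for c in node.children]
        parts.sort(key=lambda p: min(p[0]))
        prof = parts[0]
        for nxt in parts[1:]:
            prof = _merge_profiles(prof, nxt, scheme)
        return prof

    out_labels, out_rows = align_node(guide)
    order = sorted(range(len(out_labels)), key=lambda i: out_labels[i])
    return Msa([out_labels[i] for i in order], [out_rows[i] for i in order],
               scheme.kind)


# ---------------------------------------------------------------------------
# back-translation and concatenation

def backtranslate(msa_aa: Msa, cds: dict[str, str]) -> Msa:
    """Convert a protein alignment to a codon alignment.

    Each amino-acid column becomes its source codon; a gap becomes
    ``---``.  The CDS of every label must be exactly 3x the ungapped
    protein length (a trailing stop codon is trimmed); mismatches raise
    with the offending label.
    """
    rows_nt: list[str] = []
    for label, row in zip(msa_aa.labels, msa_aa.rows):
        if label not in cds:
            raise ValueError(f"no CDS for label {label!r}")
        nt = cds[label].upper()
        aa_len = len(row) - row.count(GAP)
        if len(nt) == 3 * (aa_len + 1) and nt[-3:] in ("TAA", "TAG", "TGA"):
            nt = nt[:-3]
        if len(nt) != 3 * aa_len:
            raise ValueError(
                f"label {label!r}: CDS length {len(nt)} does not match "
                f"3 x {aa_len} ungapped residues")
        out: list[str] = []
        pos = 0
        for ch in row:
            if ch == GAP:
                out.append("---")
            else:
                out.append(nt[pos : pos + 3])
                pos += 3
        rows_nt.append("".join(out))
    return Msa(list(msa_aa.labels), rows_nt, "nt")


def concatenate(alignments: list[Msa], names: list[str] | None = None) -> Msa:
    """Row-wise concatenation of alignments sharing one label set.

    Keeps a per-gene coordinate map for gene-wise bootstrap resampling.
    """
    if not alignments:
        raise ValueError("no alignments")
    base = sorted(alignments[0].labels)
    for i, m in enumerate(alignments):
        if sorted(m.labels) != base:
            missing = set(base) ^ set(m.labels)
            raise ValueError(f"alignment {i}: label set differs ({sorted(missing)})")
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(alignments))]
    rows = {l: [] for l in base}
    gene_map: list[tuple[str, int, int]] = []
    pos = 0
    for name, m in zip(names, alignments):
        for l in base:
            rows[l].append(m.row(l))
        gene_map.append((name, pos, pos + m.n_cols))
        pos += m.n_cols
    return Msa(base, ["".join(rows[l]) for l in base], alignments[0].alphabet,
               gene_map=gene_map)


# ---------------------------------------------------------------------------
# distances

def _tn_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Tajima-Nei (equal-input) distance for one encoded row pair with
    pairwise complete deletion.  Returns NaN when saturated."""
    ok = (a < 4) & (b < 4)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable columns for a sequence pair")
    av = a[ok]
    bv = b[ok]
    mism = av != bv
    p = float(mism.mean())
    if p == 0.0:
        return 0.0
    g = (np.bincount(av, minlength=4) + np.bincount(bv, minlength=4)) / (2.0 * n)
    # unordered mismatch-pair frequencies x_ij, i < j
    am = av[mism]
    bm = bv[mism]
    lo = np.minimum(am, bm).astype(np.int64)
    hi = np.maximum(am, bm).astype(np.int64)
    pair_counts = np.bincount(lo * 4 + hi, minlength=16) / n
    h = 0.0
    for i in range(4):
        for j in range(i + 1, 4):
            x = pair_counts[i * 4 + j]
            if x > 0:
                if g[i] == 0 or g[j] == 0:
                    return math.nan
                h += x * x / (2.0 * g[i] * g[j])
    b_coef = 0.5 * (1.0 - float(np.sum(g * g)) + p * p / h)
    if p >= b_coef:
        return math.nan
    return -b_coef * math.log(1.0 - p / b_coef)


def tajima_nei(msa_nt: Msa, deletion: str = "pairwise") -> DistanceMatrix:
    """Tajima-Nei distance matrix from a nucleotide alignment.

    ``deletion`` is "pairwise" (default; each pair uses every column
    where both rows are unambiguous) or "complete" (columns containing a
    gap/ambiguity in *any* row are removed once for all pairs).
    Saturated pairs (p >= b) are reported as NaN with a warning.
    """
    if msa_nt.alphabet != "nt":
        raise ValueError("nucleotide alignment required")
    if len(msa_nt.labels) < 2:
        raise ValueError("need at least 2 rows")
    codes = msa_nt.codes()
    if deletion == "complete":
        keep = (codes < 4).all(axis=0)
        codes = codes[:, keep]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = codes.shape[0]
    mat = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            d = _tn_pair(codes[i], codes[j])
            if math.isnan(d):
                saturated.append((msa_nt.labels[i], msa_nt.labels[j]))
            mat[i, j] = mat[j, i] = d
    if saturated:
        warnings.warn(f"saturated pairs reported as missing: {saturated}",
                      stacklevel=2)
    return DistanceMatrix(list(msa_nt.labels), mat)


def p_distance(msa: Msa) -> DistanceMatrix:
    """Uncorrected mismatch proportion with pairwise deletion; gap or
    ambiguity columns are excluded per pair."""
    codes = msa.codes() if msa.alphabet == "nt" else None
    if codes is None:
        arr = np.vstack([np.frombuffer(r.encode("ascii"), dtype=np.uint8)
                         for r in msa.rows])
        valid = arr != ord(GAP)
    else:
        arr = codes
        valid = arr < 4
    n = arr.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            if not ok.any():
                raise ValueError("no comparable columns for a sequence pair")
            mat[i, j] = mat[j, i] = float((arr[i][ok] != arr[j][ok]).mean())
    return DistanceMatrix(list(msa.labels), mat)


# ---------------------------------------------------------------------------
# neighbor-joining

def nj(dm: DistanceMatrix) -> Clade:
    """Saitou-Nei neighbor-joining with the standard Q-criterion.

    Ties break on the lexicographically smallest (sorted) label pair; an
    internal node inherits the smallest label among its leaves for
    tie-breaking only.  Negative branch lengths are clamped to zero with
    the deficit shifted to the sister branch.  The returned tree is
    unrooted, represented with a trifurcating root.
    """
    if not np.isfinite(dm.matrix).all():
        raise ValueError("distance matrix contains non-finite entries")
    labels = list(dm.labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    if len(labels) == 2:
        half = dm.matrix[0, 1] / 2.0
        return Clade(children=[Clade(labels[0], half), Clade(labels[1], half)])
    nodes: dict[str, Clade] = {l: Clade(l) for l in labels}
    d = {a: {b: float(dm.get(a, b)) for b in labels if b != a} for a in labels}
    active = sorted(labels)

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                a, b = active[ai], active[bi]
                q = (m - 2) * d[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d[a][b]
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = clamp(la, lb)
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = la, lb
        uname = min(a, b)
        u = Clade(children=[child_a, child_b])
        du: dict[str, float] = {}
        for c in active:
            if c in (a, b):
                continue
            du[c] = max(0.0, (d[a][c] + d[b][c] - dab) / 2.0)
            del d[c][a]
            del d[c][b]
            d[c][uname] = du[c]
        del d[a]
        del d[b]
        d[uname] = du
        nodes[uname] = u
        active = sorted(set(active) - {a, b} | {uname})

    a, b, c = active
    la = (d[a][b] + d[a][c] - d[b][c]) / 2.0
    lb = (d[a][b] + d[b][c] - d[a][c]) / 2.0
    lc = (d[a][c] + d[b][c] - d[a][b]) / 2.0
    for node, ln in ((a, la), (b, lb), (c, lc)):
        nodes[node].length = max(0.0, ln)
    return Clade(children=[nodes[a], nodes[b], nodes[c]])


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap(msa_nt: Msa, n_reps: int = 1000, seed: int = 0,
              mode: str = "column", deletion: str = "pairwise") -> Clade:
    """Neighbor-joining tree with bootstrap supports.

    Columns (or whole genes, using the concatenation coordinate map) are
    resampled with replacement; each replicate recomputes the Tajima-Nei
    matrix and NJ tree, and the support of every internal split of the
    point-estimate tree is the percentage of replicates containing it.
    Replicates with a saturated pair are dropped and counted; a warning
    is emitted when more than 20% are dropped.
    """
    if len(msa_nt.labels) < 4:
        raise ValueError("bootstrap needs at least 4 rows")
    if mode not in ("column", "gene"):
        raise ValueError("mode must be 'column' or 'gene'")
    if mode == "gene" and not msa_nt.gene_map:
        raise ValueError("gene mode requires a concatenation gene map")
    point = nj(tajima_nei(msa_nt, deletion))
    target_splits = point.splits()
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    codes = msa_nt.codes()
    L = codes.shape[1]
    dropped = 0
    used = 0
    for _ in range(n_reps):
        if mode == "column":
            cols = rng.integers(0, L, size=L)
        else:
            genes = rng.integers(0, len(msa_nt.gene_map), size=len(msa_nt.gene_map))
            cols = np.concatenate([np.arange(msa_nt.gene_map[g][1],
                                             msa_nt.gene_map[g][2]) for g in genes])
        sub = codes[:, cols]
        n = sub.shape[0]
        mat = np.zeros((n, n))
        sat = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(n):
                for j in range(i + 1, n):
                    dij = _tn_pair(sub[i], sub[j])
                    if math.isnan(dij):
                        sat = True
                        break
                    mat[i, j] = mat[j, i] = dij
                if sat:
                    break
        if sat:
            dropped += 1
            continue
        rep = nj(DistanceMatrix(list(msa_nt.labels), mat))
        used += 1
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
    if n_reps and dropped > 0.2 * n_reps:
        warnings.warn(f"{dropped}/{n_reps} bootstrap replicates dropped "
                      "(saturated pairs)", stacklevel=2)
    denom = used if used else 1
    for node in point.walk():
        if node is point or node.is_leaf:
            continue
        side = frozenset(node.leaves())
        all_leaves = frozenset(point.leaves())
        if min(all_leaves) in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            node.support = 100.0 * counts[side] / denom
    return point
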