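"""Synthetic evolved genomes with truth logs.

The generator emulates small cyanobacterial chromosomes: a single-contig
ancestor with an i.i.d. background at a target GC, non-overlapping
in-frame protein-coding genes on alternating strands (ATG start, canonical
stop), optional planted marker genes, evolved along a tree (Jukes-Cantor
multiple-hit sampling, branch lengths in expected substitutions per site)
or to a flat target pairwise divergence.  Defaults follow the compared
organisms' ranges (megabase chromosomes, mid GC, thousands of genes);
desk-scale analyses pass smaller sizes explicitly.

Every run returns a :class:`TruthLog` carrying realized per-pair aligned
identity over the known site-homology map, the ortholog pairing, and
planted marker coordinates -- the ground truth against which the taxonomy
metrics are validated.

By default substitutions that would create an in-frame internal stop are
reverted (a stand-in for purifying selection against nonsense mutations,
keeping translations valid); indels are placed in intergenic sequence at
least 30 bp away from any feature boundary, so the gene-level homology
map stays exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from numba import njit

from . import phylogeny, seqio

__all__ = ["SimConfig", "Ancestor", "TruthLog", "SimResult", "make_ancestor",
           "evolve", "diverge_proteome", "fixture_suite", "jc_expected_identity"]

DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
STOP_CODONS = ("TAA", "TAG", "TGA")
_STOP_CODES = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _to_str(codes: np.ndarray) -> str:
    return DECODE[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(128, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def jc_expected_identity(branch_length: float) -> float:
    """Expected aligned identity between two ends of a Jukes-Cantor path
    of the given total length (expected substitutions/site)."""
    return 0.25 + 0.75 * np.exp(-4.0 * branch_length / 3.0)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    ancestor_length: int = 4_000_000
    gc_target: float = 0.5
    n_genes: int = 2600
    gene_length_codons: tuple[int, int, int] = (60, 120, 250)  # min/mode/max
    tree: str | None = None           # newick, branch lengths in subs/site
    divergence: float | None = None   # flat pairwise substitution proportion
    indel_rate: float = 0.0           # per eligible intergenic site
    indel_mean: float = 3.0           # geometric length mean
    dinuc_bias: float = 0.15          # sd of the log neighbor-preference noise
    markers: dict[str, int] | None = None  # marker name -> length to plant
    repair_stops: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must be in (0, 1)")
        if self.divergence is not None and not (0.0 <= self.divergence <= 0.5):
            raise ValueError("divergence must be in [0, 0.5]")
        if not (0.0 <= self.indel_rate <= 0.5):
            raise ValueError("indel_rate must be in [0, 0.5]")


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    start: int
    end: int
    strand: str


@dataclass
class Ancestor:
    genome: seqio.GenomeRecord
    proteome: seqio.Proteome
    genes: list[GeneFeature]
    marker_coords: dict[str, tuple[int, int]]
    codes: np.ndarray


@dataclass
class TruthLog:
    pairwise_identity: dict[tuple[str, str], float]
    ortholog_pairs: dict[str, dict[str, str]]   # gene_id -> {genome -> prefixed id}
    marker_coords: dict[str, dict[str, tuple[int, int]]]  # genome -> name -> span
    branch_substitutions: dict[str, int]
    pseudogenized: list[tuple[str, str]]        # (genome, gene) with internal stop

    def identity(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.pairwise_identity else (b, a)
        return self.pairwise_identity[key]


@dataclass
class SimResult:
    genomes: dict[str, seqio.GenomeRecord]
    proteomes: dict[str, seqio.Proteome]
    truth: TruthLog


@njit(cache=True)
def _markov_walk(u: np.ndarray, cum_rows: np.ndarray, start: int) -> np.ndarray:
    out = np.empty(len(u), dtype=np.uint8)
    s = start
    for i in range(len(u)):
        row = cum_rows[s]
        j = 0
        while u[i] >= row[j] and j < 3:
            j += 1
        out[i] = j
        s = j
    return out


def _background(rng: np.random.Generator, length: int, probs: np.ndarray,
                bias: float) -> np.ndarray:
    """Background sequence with a genome-specific dinucleotide signature.

    An i.i.d. background has no neighbor structure, so its dinucleotide
    odds ratios are all ~1 and signature distances collapse; real genomes
    carry idiosyncratic neighbor preferences.  The background is therefore
    a first-order Markov chain whose transition matrix perturbs the base
    composition by seeded log-normal neighbor preferences (sd = ``bias``)
    and is iteratively rescaled so its stationary distribution matches the
    target composition.
    """
    if bias <= 0:
        return rng.choice(4, size=length, p=probs).astype(np.uint8)
    T = probs[None, :] * np.exp(rng.normal(0.0, bias, size=(4, 4)))
    T /= T.sum(axis=1, keepdims=True)
    for _ in range(20):  # pin the stationary distribution to `probs`
        evals, evecs = np.linalg.eig(T.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi = np.abs(pi) / np.abs(pi).sum()
        T = T * (probs / pi)[None, :]
        T /= T.sum(axis=1, keepdims=True)
    cum = np.cumsum(T, axis=1)
    cum[:, 3] = 1.0
    u = rng.random(length)
    start = int(rng.choice(4, p=probs))
    return _markov_walk(u, cum, start)


def _random_codons(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    """n sense codons (no stop) as a flat code array of length 3n."""
    out = np.empty((n, 3), dtype=np.uint8)
    filled = 0
    while filled < n:
        cand = rng.choice(4, size=(n - filled, 3), p=probs).astype(np.uint8)
        ok = np.array([tuple(c) not in _STOP_CODES for c in cand])
        good = cand[ok]
        out[filled : filled + len(good)] = good
        filled += len(good)
    return out.reshape(-1)


def make_ancestor(cfg: SimConfig, genome_id: str = "ancestor") -> Ancestor:
    """Build the ancestral genome, proteome and feature table.

    Genes (and markers) are placed at uniform spacing on alternating
    strands; infeasible packing raises.
    """
    rng = np.random.default_rng(cfg.seed)
    gc = cfg.gc_target
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    lo, mode, hi = cfg.gene_length_codons
    if cfg.n_genes * hi * 3 > cfg.ancestor_length / 2:
        raise ValueError("infeasible packing: n_genes x max gene length "
                         "exceeds half the ancestor length")
    codes = _background(rng, cfg.ancestor_length, probs, cfg.dinuc_bias)

    markers = cfg.markers or {}
    n_feats = cfg.n_genes + len(markers)
    slot = cfg.ancestor_length // n_feats
    genes: list[GeneFeature] = []
    marker_coords: dict[str, tuple[int, int]] = {}
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    width = len(str(cfg.n_genes))
    feat_idx = 0
    for gi in range(cfg.n_genes):
        n_codons = int(np.rint(rng.triangular(lo, mode, hi)))
        length = 3 * (n_codons + 2)  # ATG + body + stop
        start = feat_idx * slot + max(40, (slot - length) // 2)
        end = start + length
        if end + 40 > (feat_idx + 1) * slot:
            raise ValueError("infeasible packing: gene does not fit its slot")
        body = _random_codons(rng, n_codons, probs)
        stop = _encode(STOP_CODONS[rng.integers(len(STOP_CODONS))])
        cds = np.concatenate([_encode("ATG"), body, stop])
        strand = "+" if gi % 2 == 0 else "-"
        placed = cds if strand == "+" else (3 - cds)[::-1]
        codes[start:end] = placed
        gid = f"g{gi + 1:0{width}d}"
        genes.append(GeneFeature(gid, start, end, strand))
        cds_str = _to_str(cds)
        proteins[gid] = str(Seq(cds_str).translate()).rstrip("*")
        cds_map[gid] = cds_str
        feat_idx += 1
    for name, mlen in sorted(markers.items()):
        start = feat_idx * slot + max(40, (slot - mlen) // 2)
        end = start + mlen
        if end + 40 > (feat_idx + 1) * slot:
            raise ValueError("infeasible packing: marker does not fit its slot")
        codes[start:end] = rng.choice(4, size=mlen, p=probs).astype(np.uint8)
        marker_coords[name] = (start, end)
        feat_idx += 1

    genome = seqio.GenomeRecord(genome_id, [("chr", _to_str(codes))],
                                {"source": "simulated"})
    proteome = seqio.Proteome(genome_id, proteins, cds_map)
    return Ancestor(genome, proteome, genes, marker_coords, codes)


def _jc_branch(codes: np.ndarray, bl: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Jukes-Cantor evolution along one branch: per-site Poisson event
    counts, exact multiple-hit distribution of the final base."""
    out = codes.copy()
    if bl <= 0:
        return out, 0
    k = rng.poisson(bl, size=len(codes))
    hit = np.flatnonzero(k > 0)
    if len(hit) == 0:
        return out, 0
    p_stay = 0.25 + 0.75 * (-1.0 / 3.0) ** k[hit]
    change = hit[rng.random(len(hit)) >= p_stay]
    out[change] = (out[change] + rng.integers(1, 4, size=len(change)).astype(np.uint8)) % 4
    return out, int(len(change))


def _flat_divergence(codes: np.ndarray, p: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Substitute a Bernoulli(p) fraction of sites, each to a different base."""
    out = codes.copy()
    sites = np.flatnonzero(rng.random(len(codes)) < p)
    out[sites] = (out[sites] + rng.integers(1, 4, size=len(sites)).astype(np.uint8)) % 4
    return out, int(len(sites))


def _repair_stops(leaf: np.ndarray, anc: Ancestor) -> list[str]:
    """Revert substitutions creating in-frame internal stops; returns gene
    ids that still carry one afterwards (none when ancestors are clean)."""
    bad: list[str] = []
    for gene in anc.genes:
        if gene.strand == "+":
            cds = leaf[gene.start : gene.end]
            ref = anc.codes[gene.start : gene.end]
        else:
            cds = (3 - leaf[gene.start : gene.end])[::-1]
            ref = (3 - anc.codes[gene.start : gene.end])[::-1]
        n_codons = len(cds) // 3
        changed = False
        for c in range(1, n_codons - 1):
            tri = tuple(int(x) for x in cds[3 * c : 3 * c + 3])
            if tri in _STOP_CODES:
                cds[3 * c : 3 * c + 3] = ref[3 * c : 3 * c + 3]
                changed = True
        if changed:
            if gene.strand == "+":
                leaf[gene.start : gene.end] = cds
            else:
                leaf[gene.start : gene.end] = (3 - cds)[::-1]
    return bad


def _find_internal_stops(leaf: np.ndarray, anc: Ancestor) -> list[str]:
    out = []
    for gene in anc.genes:
        if gene.strand == "+":
            cds = leaf[gene.start : gene.end]
        else:
            cds = (3 - leaf[gene.start : gene.end])[::-1]
        n_codons = len(cds) // 3
        for c in range(1, n_codons - 1):
            if tuple(int(x) for x in cds[3 * c : 3 * c + 3]) in _STOP_CODES:
                out.append(gene.gene_id)
                break
    return out


def _protected_mask(anc: Ancestor, pad: int = 30) -> np.ndarray:
    mask = np.zeros(len(anc.codes), dtype=bool)
    spans = [(g.start, g.end) for g in anc.genes] + list(anc.marker_coords.values())
    for start, end in spans:
        mask[max(0, start - pad) : min(len(mask), end + pad)] = True
    return mask


def _apply_indels(codes: np.ndarray, anc: Ancestor, cfg: SimConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, dict[int, str], np.ndarray]:
    """Sample intergenic indels; returns (codes, insertions, deleted mask)."""
    deleted = np.zeros(len(codes), dtype=bool)
    insertions: dict[int, str] = {}
    if cfg.indel_rate <= 0:
        return codes, insertions, deleted
    protected = _protected_mask(anc)
    eligible = np.flatnonzero(~protected)
    events = eligible[rng.random(len(eligible)) < cfg.indel_rate]
    for pos in events:
        length = int(rng.geometric(1.0 / cfg.indel_mean))
        if rng.random() < 0.5:
            stop = pos
            while stop < len(codes) and stop - pos < length and not protected[stop]:
                stop += 1
            deleted[pos:stop] = True
        else:
            ins = rng.integers(0, 4, size=length).astype(np.uint8)
            insertions[int(pos)] = _to_str(ins)
    return codes, insertions, deleted


def _materialize(codes: np.ndarray, insertions: dict[int, str],
                 deleted: np.ndarray) -> str:
    if not insertions and not deleted.any():
        return _to_str(codes)
    pieces: list[str] = []
    last = 0
    breakpoints = sorted(insertions)
    for pos in breakpoints:
        pieces.append(_to_str(codes[last:pos][~deleted[last:pos]]))
        pieces.append(insertions[pos])
        last = pos
    pieces.append(_to_str(codes[last:][~deleted[last:]]))
    return "".join(pieces)


def _shifted_span(start: int, end: int, insertions: dict[int, str],
                  deleted: np.ndarray) -> tuple[int, int]:
    ins_before = sum(len(s) for p, s in insertions.items() if p <= start)
    del_before = int(deleted[:start].sum())
    shift = ins_before - del_before
    return start + shift, end + shift


def evolve(anc: Ancestor, cfg: SimConfig) -> SimResult:
    """Evolve the ancestor along ``cfg.tree`` (Jukes-Cantor) or to the flat
    pairwise divergence ``cfg.divergence`` (two leaves, "A" and "B")."""
    rng = np.random.default_rng(cfg.seed + 1)
    leaf_codes: dict[str, np.ndarray] = {}
    branch_subs: dict[str, int] = {}

    if cfg.divergence is not None:
        leaf_codes["A"] = anc.codes.copy()
        branch_subs["A"] = 0
        leaf_codes["B"], branch_subs["B"] = _flat_divergence(anc.codes, cfg.divergence, rng)
    elif cfg.tree is not None:
        tree = phylogeny.parse_newick(cfg.tree)

        def walk(node: phylogeny.Clade, codes: np.ndarray) -> None:
            for child in node.children:
                evolved, nsub = _jc_branch(codes, child.length or 0.0, rng)
                if child.is_leaf:
                    if child.name is None:
                        raise ValueError("tree leaves must be named")
                    leaf_codes[child.name] = evolved
                    branch_subs[child.name] = nsub
                else:
                    walk(child, evolved)

        walk(tree, anc.codes)
    else:
        raise ValueError("SimConfig needs either a tree or a flat divergence")

    pseudo: list[tuple[str, str]] = []
    genomes: dict[str, seqio.GenomeRecord] = {}
    proteomes: dict[str, seqio.Proteome] = {}
    marker_coords: dict[str, dict[str, tuple[int, int]]] = {}
    deletions: dict[str, np.ndarray] = {}
    for label in sorted(leaf_codes):
        codes = leaf_codes[label]
        if cfg.repair_stops:
            _repair_stops(codes, anc)
        for gid in _find_internal_stops(codes, anc):
            pseudo.append((label, gid))
        codes, insertions, deleted = _apply_indels(codes, anc, cfg, rng)
        leaf_codes[label] = codes
        deletions[label] = deleted
        genomes[label] = seqio.GenomeRecord(
            label, [("chr", _materialize(codes, insertions, deleted))],
            {"source": "simulated"})
        proteins: dict[str, str] = {}
        cds_map: dict[str, str] = {}
        for gene in anc.genes:
            if gene.strand == "+":
                cds = codes[gene.start : gene.end]
            else:
                cds = (3 - codes[gene.start : gene.end])[::-1]
            cds_str = _to_str(cds)
            cds_map[gene.gene_id] = cds_str
            proteins[gene.gene_id] = str(Seq(cds_str).translate()).rstrip("*")
        try:
            proteomes[label] = seqio.Proteome(label, proteins, cds_map)
        except ValueError:
            # internal stops with repair disabled: keep proteins, drop CDS pairing
            proteomes[label] = seqio.Proteome(label, proteins, None)
        marker_coords[label] = {
            name: _shifted_span(s, e, insertions, deleted)
            for name, (s, e) in anc.marker_coords.items()}

    labels = sorted(leaf_codes)
    pairwise: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            keep = ~deletions[a] & ~deletions[b]
            pairwise[(a, b)] = float(
                (leaf_codes[a][keep] == leaf_codes[b][keep]).mean())
    ortho = {g.gene_id: {lab: f"{lab}|{g.gene_id}" for lab in labels}
             for g in anc.genes}
    truth = TruthLog(pairwise, ortho, marker_coords, branch_subs, pseudo)
    return SimResult(genomes, proteomes, truth)


def diverge_proteome(anc: Ancestor, p_aa: float, seed: int,
                     genome_id: str) -> seqio.Proteome:
    """Protein-level divergence: each residue substituted with probability
    ``p_aa`` to a uniformly chosen different amino acid; the codon of a
    changed residue is resampled from the new residue's codons, so the CDS
    pairing stays translation-consistent."""
    from Bio.Data.CodonTable import standard_dna_table

    codons_of: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        codons_of.setdefault(aa, []).append(codon)
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    for gid in sorted(anc.proteome.proteins):
        prot = anc.proteome.proteins[gid]
        cds = anc.proteome.cds[gid]
        chars = list(prot)
        codons = [cds[3 * i : 3 * i + 3] for i in range(len(cds) // 3)]
        for i, aa in enumerate(chars):
            if rng.random() < p_aa:
                alt = [x for x in AA20 if x != aa]
                new = alt[int(rng.integers(len(alt)))]
                chars[i] = new
                opts = sorted(codons_of[new])
                codons[i] = opts[int(rng.integers(len(opts)))]
        proteins[gid] = "".join(chars)
        cds_map[gid] = "".join(codons)
    return seqio.Proteome(genome_id, proteins, cds_map)


# ---------------------------------------------------------------------------
# named fixture scenarios

_SCENARIOS = ("two_species", "two_clades", "ortholog_families", "marker_set")


def fixture_suite(name: str, seed: int = 42, out_dir: str | Path | None = None) -> dict:
    """Generate a named validation scenario; optionally write FASTA inputs
    plus a truth JSON with fixed, documented seeds.

    * ``two_species``  -- 3 genomes, exactly one conspecific pair (A, B).
    * ``two_clades``   -- 8 genomes on a two-clade tree (deep split).
    * ``ortholog_families`` -- 3 proteomes x 50 single-copy families.
    * ``marker_set``   -- 4 genomes with the 5 MLSA markers planted.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {_SCENARIOS}")
    result: dict = {"scenario": name, "seed": seed}
    if name == "two_species":
        cfg = SimConfig(seed=seed, ancestor_length=80_000, n_genes=50,
                        gene_length_codons=(80, 140, 220),
                        tree="(A:0.005,B:0.005,C:0.115);")
        anc = make_ancestor(cfg)
        sim = evolve(anc, cfg)
        result.update(sim=sim, config=cfg,
                      conspecific_pair=("A", "B"), tree=cfg.tree)
    elif name == "two_clades":
        tree = ("(((A1:0.02,A2:0.02):0.02,(A3:0.02,A4:0.02):0.02):0.04,"
                "((B1:0.02,B2:0.02):0.02,(B3:0.02,B4:0.02):0.02):0.04);")
        cfg = SimConfig(seed=seed, ancestor_length=40_000, n_genes=30,
                        gene_length_codons=(100, 150, 200), tree=tree)
        anc = make_ancestor(cfg)
        sim = evolve(anc, cfg)
        result.update(sim=sim, config=cfg, tree=tree,
                      clades=(("A1", "A2", "A3", "A4"), ("B1", "B2", "B3", "B4")))
    elif name == "ortholog_families":
        cfg = SimConfig(seed=seed, ancestor_length=60_000, n_genes=50,
                        gene_length_codons=(80, 130, 200))
        anc = make_ancestor(cfg)
        proteomes = {f"G{i}": diverge_proteome(anc, 0.10, seed + i, f"G{i}")
                     for i in (1, 2, 3)}
        result.update(ancestor=anc, proteomes=proteomes, n_families=50)
    else:  # marker_set
        cfg = SimConfig(seed=seed, ancestor_length=60_000, n_genes=20,
                        gene_length_codons=(80, 120, 180),
                        tree="(M1:0.01,M2:0.01,M3:0.03,M4:0.03);",
                        markers={"rrsA": 1500, "gyrB": 900, "pyrH": 700,
                                 "recA": 1050, "rpoB": 1200})
        anc = make_ancestor(cfg)
        sim = evolve(anc, cfg)
        refs = {nm: anc.genome.sequence()[s:e]
                for nm, (s, e) in anc.marker_coords.items()}
        result.update(sim=sim, config=cfg, refs=refs)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth: dict = {"scenario": name, "seed": seed}
        if "sim" in result:
            sim = result["sim"]
            for label, g in sim.genomes.items():
                seqio.write_fasta(g.contigs, out / f"{label}.fna")
            for label, p in sim.proteomes.items():
                seqio.write_fasta(sorted(p.proteins.items()), out / f"{label}.faa")
                if p.cds:
                    seqio.write_fasta(sorted(p.cds.items()), out / f"{label}.ffn")
            truth["pairwise_identity"] = {
                f"{a}|{b}": v for (a, b), v in sim.truth.pairwise_identity.items()}
            truth["marker_coords"] = sim.truth.marker_coords
            if "tree" in result:
                truth["tree"] = result["tree"]
        if "proteomes" in result:
            for label, p in result["proteomes"].items():
                seqio.write_fasta(sorted(p.proteins.items()), out / f"{label}.faa")
                seqio.write_fasta(sorted(p.cds.items()), out / f"{label}.ffn")
        if "refs" in result:
            seqio.write_fasta(sorted(result["refs"].items()), out / "markers.fna")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return result
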