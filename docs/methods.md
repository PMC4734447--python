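# Methods

This note documents the models and procedures implemented in `gentaxo`,
the defaults chosen where the underlying conventions leave room, and
what the synthetic-data validation does and does not establish.

## Coordinates and sequence handling

All coordinates are 0-based half-open.  Sequences are stored uppercase.
IUPAC ambiguity codes are kept verbatim in nucleotide records but are
(a) excluded from GC computation, (b) scored as mismatches by the
alignment kernels, and (c) skipped in dinucleotide counting.  GC% is
reported to two decimals in tabular output.

Genome fragmentation for ANI tiles each contig with non-overlapping
windows of `frag_len` (default 1,020 bp).  A terminal remainder is kept
as a shorter fragment when it is at least half the window and dropped
otherwise: very short fragments carry noisy identity estimates and would
bias the per-fragment mean.

## Alignment kernels

Pairwise alignment is affine-gap (Gotoh three-state) dynamic programming
with a gap of length L costing `gap_open + L*gap_extend` (defaults 11
and 1).  Nucleotide scoring is +1/−2; proteins use BLOSUM62 (loaded from
Biopython's matrix collection).

* Nucleotide local search is seed-and-extend: exact 11-mer seeds are
  located on the subject for both query strands (the minus strand by
  reverse-complementing the query, so subject coordinates stay forward);
  seeds within a 32-diagonal drift are clustered, the strongest cluster
  is chosen (tie: plus strand), and a Smith–Waterman pass restricted to
  a subject window around the seeded diagonals recovers the alignment.
  For subjects up to four query lengths the window is the whole subject,
  making the result identical to exhaustive DP whenever a seed exists.
  A pair with no seed on either strand is reported as "no alignment",
  not as an error.
* Protein search is exhaustive Smith–Waterman — proteome sizes here make
  the full DP affordable — optionally prefiltered by shared exact 4-mers
  (a pair sharing no 4-mer cannot produce a meaningful hit; the filter
  can only skip pairs, never change a computed alignment).
* Global alignment is Needleman–Wunsch end to end; identity is counted
  over all columns, a gap column being a non-identity.

Statistics follow the Karlin–Altschul convention:
`bitscore = (λ·S − ln K)/ln 2`, `evalue = m·n·2^(−bitscore)` with m the
query length and n the database size.  The default gapped constants
(BLOSUM62: λ = 0.267, K = 0.041; +1/−2 nucleotide: λ = 1.28, K = 0.46)
are standard published values, exposed as configuration and recorded in
reports; they are conventions, not fitted quantities.

## Taxonomy metrics

**ANI.**  A fragment is retained when its best local alignment reaches
≥ 30% identity over ≥ 70% of the fragment length; these thresholds and
the 1,020-bp fragment are the fragment-based ANI lineage's convention
and are CLI-exposed.  One-way ANI is the mean identity over retained
fragments; the two-way value is the arithmetic mean of the one-way
means (a pooled-fragment mean is available from the per-direction
results).  Zero retained fragments yield an explicit no-signal state —
never a 0 — and a no-signal direction is excluded from the two-way mean.
N-containing columns count as mismatches.

**AAI.**  Reciprocal best hits by bit score (ties: higher identity, then
lexicographically smaller subject id), filtered at 30% identity and 70%
coverage of the shorter protein; AAI is the mean identity of surviving
pairs.  The proteome pair is canonicalized by genome id before
searching, making AAI exactly symmetric.

**Dinucleotide signature.**  Frequencies are computed per contig on the
contig concatenated with its reverse complement (Karlin's convention,
which makes the profile strand-invariant by construction); dinucleotides
are not counted across contig junctions or the concatenation seam.  The
δ distance is reported on the raw scale, where 0.01 is the conventional
same-species ceiling; the ×1000 display convention is a formatting
option only.  δ is a scaled L1 metric, hence symmetric and
triangle-inequality-compliant.

**In-silico DDH.**  The genome distance pools identical and total
alignment columns over every retained ANI fragment in both directions
(the identities/alignment-length formula family), making d symmetric by
construction.  The logistic map `DDH = 100/(1 + exp(α + β·d))` requires
β > 0 and ≥ 99% predicted DDH at d = 0.  The bundled default
(α = −5, β = 83) is a calibration on this package's own simulator chosen
so that d = 0.05 sits at the classical 70% boundary — i.e. the DDH
verdict agrees with the 95% ANI boundary on simulated data.  It is
explicitly a calibration, not a literature regression; site-specific
models can be supplied as a JSON file.

**Markers / MLSA.**  Markers are discovered by homology to user-supplied
reference sequences (no HMM scan; references are free configuration
because no extraction protocol is canonical).  A hit must cover ≥ 50% of
the reference; minus-strand hits are reverse-complemented to reference
orientation.  MLSA aligns each marker across genomes (progressive MSA),
concatenates the alignments in the fixed order rrsA, gyrB, pyrH, recA,
rpoB, pads missing markers with gap columns (keeping the matrix
complete), and reports p-distances by default (Tajima–Nei optional).
Genomes carrying fewer than 3 of the 5 markers are excluded so gap
padding cannot dominate a row.

**Classification.**  Verdicts are inclusive on the same-species side
(ANI ≥ 95, AAI ≥ 95, DDH ≥ 70, δ ≤ 0.01), since failures are
conventionally phrased as falling below/above the cutoffs.  The
consensus — same-species iff every available identity verdict (ANI, AAI,
DDH) is same-species and the δ verdict is not different — is this
package's own combiner, labeled as such in reports; the metrics are
classically applied side by side without a formal rule.

## Pangenome clustering

The similarity graph keeps every alignment with e-value ≤ 1e-5, weighted
−log10(e-value) capped at 200; within-genome edges are kept so paralogs
cluster.  MCL runs on the column-stochastic matrix with self-loops set
to each node's maximum incident weight, alternating expansion (matrix
square) and inflation (entrywise power 1.25, column renormalization)
with pruning below 1e-5, until the matrix change falls below 1e-6 (cap
100 iterations, warning on non-convergence).  Clusters are connected
components of the converged support; genes with no qualifying edge form
singleton groups, so groups always partition the gene set.  Nodes are
sorted lexicographically before matrix construction, making cluster ids
stable and the output independent of input order.

The classical OrthoMCL pipeline additionally normalizes inter-genome
weights by within-genome averages; since only the inflation factor and
e-value cutoff of that pipeline are canonical, plain MCL on
−log10(e-value) weights is the default here and the normalization is a
flag recorded in output metadata.  In the summary, `n_groups` counts
multi-gene homologous groups; singleton groups are the orphans (no
ortholog, no paralog), and exclusive genes split exactly into orphans
plus exclusive-with-paralog.

## Phylogenomics

Progressive MSA builds a guide tree by neighbor-joining on k-mer cosine
distances (k = 3 for proteins, 6 for nucleotides) and merges profiles
leaf-to-root by affine-gap profile–profile global alignment scored with
mean column substitution scores.  All ties resolve on lexicographic
label order, so the alignment is independent of input order.  This is a
single-pass progressive aligner: it does not implement iterative
refinement, which is unnecessary at the within-family divergences the
pipeline feeds it.

Back-translation maps each amino-acid column onto its source codon
(gap → `---`), after verifying that each CDS is exactly 3× the ungapped
protein length modulo a trailing stop.  Concatenation requires identical
label sets and retains a per-gene coordinate map.

Tajima–Nei distances use the equal-input correction
`d = −b·ln(1 − p/b)` with `b = ½(1 − Σ gᵢ² + p²/h)` and
`h = Σ_{i<j} x_ij²/(2 gᵢ gⱼ)`, where gᵢ are the pair-pooled base
frequencies and x_ij the unordered mismatch-pair frequencies.  Deletion
is pairwise by default (each pair uses every column where both rows are
unambiguous — maximizes signal); complete deletion is a flag.  A
saturated pair (p ≥ b) is reported as missing with a warning, never
silently clamped.

Neighbor-joining is the Saitou–Nei agglomeration on the standard
Q-criterion with deterministic tie-breaking (lexicographically smallest
label pair; an internal node inherits the smallest leaf label for
comparison only).  Negative branch lengths are clamped to zero with the
deficit shifted to the sister branch.  The output is unrooted,
represented with a trifurcating root; Newick serialization writes branch
lengths to 6 decimals and bootstrap supports as internal node labels.

Bootstrap resamples alignment columns with replacement by default; a
gene-wise mode (resampling whole genes via the concatenation map) is
provided because for a concatenated-gene matrix either resampling unit
is defensible.  Supports are the percentage of replicates containing
each internal split of the point-estimate tree; replicates with a
saturated pair are dropped and counted, with a warning above 20%.

## Synthetic data

The generator emulates small cyanobacterial chromosomes: a single-contig
ancestor with a target GC, non-overlapping in-frame genes (ATG +
stop-free body + canonical stop) on alternating strands at uniform
spacing, and optional planted marker genes.  The background is a
first-order Markov chain whose transition matrix perturbs the base
composition with seeded log-normal neighbor preferences (sd 0.15),
iteratively rescaled so the stationary composition hits the GC target:
an i.i.d. background has no dinucleotide structure (all odds ratios ≈ 1),
whereas real genomes carry idiosyncratic signatures — the Markov
background gives each simulated genome one.

Evolution is Jukes–Cantor along a user tree (per-site Poisson event
counts with the exact multiple-hit distribution of the final base,
branch lengths in expected substitutions/site) or a flat Bernoulli(p)
substitution to a different base (realized divergence = p exactly, up to
binomial noise).  Substitutions creating an in-frame internal stop are
reverted by default — a stand-in for purifying selection against
nonsense mutations that keeps every descendant CDS translation-
consistent; the truth log is computed *after* repair, so realized
identities remain exact.  Indels (geometric lengths, mean 3) are placed
only in intergenic sequence ≥ 30 bp from any feature boundary, keeping
the gene-level homology map exact.  Protein-level scenarios substitute
residues directly at a target amino-acid divergence and resample the
codon of each changed residue, preserving CDS/protein consistency.

The truth log records realized per-pair aligned identity over the known
site-homology map, ortholog pairing, per-branch substitution counts and
marker coordinates.  Same seed ⇒ byte-identical fixtures.

**What the validation shows — and does not.**  Simulated genomes have
uniform substitution rates, no rearrangements, no horizontal transfer,
no rate heterogeneity across sites, and gene repertoires identical
across taxa.  Passing tests therefore establish that the *metrics and
algorithms* are implemented correctly and recover planted truth; they do
not establish robustness to the full complexity of real genomes (biased
gene loss, mobile elements, compositional heterogeneity within a
replicon).  Headline counts from real multi-genome datasets (numbers of
homolog groups, core sizes, orphan counts) depend on the exact external
sequence and annotation versions and are deliberately not reproduction
targets; the pipeline emits these statistics for any input set.

## Problem sizes used in validation

Desk-scale sizes were chosen so each property is measured with clear
statistical margin: 40–80-kb genomes for identity/self checks, 200-kb
pairs for the divergence ladder (binomial noise on p is ~0.001 there),
3 genomes × 50 families for clustering truth, 8 taxa × 30 genes
(~13.5-kb concatenated alignment) with 100 bootstrap replicates for the
two-clade fixture, and 50 random 5–10-taxon additive trees for NJ.
Bootstrap replicate counts and genome sizes are parameters throughout;
production-scale runs simply pass larger values.
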