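# Methods

This note records the models, conventions and design choices behind each
module, what the synthetic data emulate, and the known limitations.

## Coordinates and formats

Internal arithmetic uses 0-based half-open intervals; every I/O boundary
(FASTA, GFF3, locus strings such as `chr3D: 600607844-600608597`,
reports) is 1-based inclusive, converted exactly at the boundary.
Subgenome labels derive deterministically from the chromosome name's
trailing letter (A/B/D; anything else is unanchored, "U"). Ambiguity
codes are kept verbatim and never dropped. ORF lengths in the packaged
family table follow the convention `orf_bp = 3·(aa_len + 1)`, i.e. the
stop codon is counted; the table validates this invariant on load.

Exon–intron inference from a CDS and its genomic sequence assumes exact
spliced identity (no sequencing error): exons are maximal exact-match
blocks found by greedy longest-prefix matching, with leftmost
(intron-minimal) placement on ties. The synthetic generator keeps splice
boundaries unambiguous (the first/last intron base differs from the
adjacent CDS base), so planted structures are recovered exactly; on real
data with boundary ambiguity the leftmost convention decides. UTRs can
come either from the annotation or from CDS/genomic comparison; the
structure records its provenance.

## Protein physicochemistry

Molecular weight is the sum of average (not monoisotopic) residue masses
plus one water (18.01524 Da). The isoelectric point solves the Bjellqvist
charge model — side-chain pKa for D, E, C, Y, H, K, R plus
residue-specific terminal pKas — by bisection on [0, 14] to
|charge| < 1e−4 (max 200 iterations; the charge is strictly decreasing in
pH so the root is unique). GRAVY is the unweighted mean Kyte–Doolittle
hydropathy. The pKa table is a swappable argument; the default is the set
used by ExPASy ProtParam, because the published per-protein values were
produced there. One subtlety: with residue-specific *terminal* pKas,
appending an acidic residue re-assigns the C-terminal group (3.55 →
4.55/4.75) and can marginally raise the pI even though a negative side
chain was added; the monotonicity property therefore holds (and is
tested) under a fixed-terminal pKa set. Rounding (2 decimals for kDa and
pI, 3 for GRAVY) happens only at the reporting layer.

The mean of the packaged table's GRAVY column is −1.228; family means of
protein length, Mw and pI (154 aa, 16.84 kDa, 8.05) are exact acceptance
surfaces, mean ORF length (465.7 bp) is reported but not asserted
exactly.

## Alignment, E-values and profile search

The aligner is an exact Gotoh dynamic program; no heuristic seeding. A
gap of length L costs `gap_open + (L−1)·gap_extend` (defaults −11/−1 with
BLOSUM62). Traceback ties resolve diagonal > up > left, so alignments are
reproducible. Identity is counted over aligned columns with internal gap
columns in the denominator (local alignments have no end gaps by
construction). E-values use the Karlin–Altschul form `E = K·m·n·e^{−λS}`
with the published gapped BLOSUM62 parameters λ = 0.267, K = 0.041,
configurable per matrix.

The family search deliberately replaces a profile-HMM with a transparent
ungapped-column log-odds profile (half-bit units, so the same (λ, K)
apply) searched by affine-gap local alignment, at the same thresholds
(E ≤ 1e−10; domain completeness = match span ≥ 80% of profile width).
Columns with > 50% gaps are dropped; +0.1 pseudocount per residue;
uniform background unless supplied. Redundancy removal collapses
sequences at 100% identity to the lexicographically smallest id
(configurable down to 99% via the identity threshold of the pair stage),
keeping all member ids in the row.

## Phylogeny

The progressive aligner builds a guide tree from fractional-common-3-mer
distances and NJ, then merges profiles in postorder by global
profile–profile alignment (column score = frequency-weighted mean
BLOSUM62 score of non-gap residue pairs; gaps −10/−1). The aligner never
edits residues — degapping any row reproduces its input, and that is
asserted at run time.

Distances use pairwise deletion of gap-containing column pairs. Models:
p-distance; Poisson correction −ln(1−p) (saturated pairs flagged); and
`jtt_ml`, the maximum-likelihood scalar time under the JTT empirical
rate matrix, optimized per pair by bounded 1-D search of the pairwise
likelihood. The JTT matrix exponential is computed once by
eigendecomposition (π^½ symmetrization) and cached.

Neighbor joining follows Saitou–Nei with the standard Q criterion; ties
take the smallest (i, j) index pair; negative branch estimates are
clamped to zero and counted. Additive matrices are reproduced exactly
(tested against a four-point oracle and cross-checked against
scikit-bio's NJ). Bootstrap supports are the percentage of
column-resampled replicate trees containing each original bipartition;
the replicate stream is a `numpy` Generator seeded by the caller, so runs
are reproducible. Groups are extracted by removing the k−1 longest
internal edges (ties by edge creation id) — the operationalization chosen
for "k groups", since visual tree delimitation has no algorithmic
definition — or by nearest labeled reference leaf. The tree serializes to
Newick with supports as internal node labels. Distance-based NJ was
implemented rather than likelihood tree search; rooting and outgroup
inference are out of scope.

## Duplication classification

Homolog pairs require, strictly, E < 1e−20 *and* identity > 75%.
Separation is measured between nearer gene ends (bases strictly between
the upstream gene's end and the downstream gene's start); midpoint
distances are not used. Tandem arrays are maximal chains of consecutive
family genes on one chromosome whose separations are ≤ 150 kb and which
are pairwise homologous; with a full annotation the no-intervening-gene
rule is enforced, without one the run is in family-only mode (only family
genes can break a chain) and says so. Both counting conventions are
exposed: arrays and consecutive pairs (`n_pairs = members − 1`).
Unanchored genes are excluded from tandem/segmental calls and reported
separately. Homoeolog groups are connected components of the
cross-subgenome homolog graph; the canonical member per subgenome
maximizes mean identity to the other subgenomes (ties by gene id), and
surplus same-subgenome members are flagged expansion copies. Ka/Ks dating
and synteny-block detection are out of scope.

## Motif discovery and promoter scanning

Discovery fits a ZOOPS (zero-or-one occurrence per sequence) mixture by
EM, the model class matching the default of standard motif-discovery
tools for protein families. Initialization is deterministic: the most
frequent exact word of the candidate width (ties lexicographic) seeds the
PWM at 0.6 match probability. The M-step adds a +0.1 Dirichlet
pseudocount per cell, so the monotone quantity is the MAP objective
(likelihood × prior); it is asserted non-decreasing every iteration.
Width selection is a coarse grid then a ±(step−1) refinement, scored by a
BIC-style penalty `0.5·(w·(k_eff−1)+1)·ln(n_seq)` where k_eff counts
residues actually present in the input (absent residues are not
estimable parameters). Accepted motifs mask their MAP sites (posterior
site probability > 0.5) before the next round; discovery stops when no
width scores above the penalty or after `max_motifs`. The background is
the observed residue frequency of the input set.

Promoters are the 2000 bp upstream of the annotated gene start,
strand-corrected (minus-strand promoters are reverse-complemented) and
truncated at contig edges with the realized length recorded. Scanning
scores every window on both strands with log2(p/bg) log-odds discretized
to 0.01-bit integer steps; the p-value of a score is the exact tail
probability of the discretized score under the background, computed by
convolving the per-column score distributions. The default per-window
threshold is p ≤ 1e−4. This replaces a web server's opaque binding-site
prediction with a transparent, user-supplied-PWM scan; server-side
thresholds ("top N" settings, server E-values) have no client-side
equivalent, so genome-wide hit totals from such servers are not
comparable quantities.

## Expression and qPCR

FPKM matrices are transformed elementwise to log2(FPKM+1). Heatmap row
order comes from average-linkage hierarchical clustering on Euclidean
distances of the transformed rows (scipy's standard recursive leaf
ordering; linkage is configurable — display ordering is not an asserted
quantity). ΔΔCT follows the Livak convention: per-replicate
ΔCT = Ct(target) − Ct(reference); ΔΔCT is the difference of treated and
control mean ΔCT (not per-replicate pairing); fold change = 2^−ΔΔCT.
Significance is a two-sided Welch t-test on replicate ΔCT values — chosen
over the pooled-variance Student's test as the safer default when only
"t test" is specified, and switchable to pooled. Calls: up if fold > 1
and p ≤ 0.05, down if fold < 1 and p ≤ 0.05, else ns, with the 0.01 level
also reported.

## Synthetic data

The generator emulates the structures the analysis assumes: an ancestral
family protein (JTT stationary composition, default 150 aa) evolved into
group ancestors at a between-group identity target (default 0.45) and
into homoeolog triads at a within-triad target (default 0.96), by
per-site substitution with JTT-conditional replacements so distance
recovery is model-consistent. Each copy mutates a fraction (1 − target)/2
so pairwise identities land near the target (checked to ±5 points).
Tandem arrays are placed with spacings drawn from U[5 kb, 200 kb] —
deliberately straddling the 150-kb rule so both sides are exercised;
non-array genes are separated by 250–320 kb. Genes are back-translated
with random synonymous codons, split into two exons around a 50–500 bp
intron, and placed with 2-kb promoters carrying planted PWM consensus
sites at recorded offsets. Decoys are residue shuffles of family proteins
(same composition, destroyed order). A paper-shaped preset produces 33
genes in six groups of 10/3/3/5/5/7, with the 7-member group
sequence-identical (six tandem copies plus one unanchored scaffold copy),
triads on chromosome groups 2/3/4, and a B/D-only pair. Expression
matrices are log-normal with group-by-condition means and optional exact
tissue-specific zeros; Ct tables plant ΔΔCT effects (default replicate
noise sd 0.2, 3 replicates) over the factorial {NaCl 6/24 h, PEG 6/48 h}
× {leaf, root} design.

What the synthetic data do *not* emulate: intergenic repeat structure and
GC skew, splice-site sequence signals, read-level noise in FPKM values,
amplification-efficiency variation in qPCR, and alignment ambiguity from
real indel processes. Passing recovery tests therefore demonstrates
correctness of the algorithms under the stated generative assumptions,
not robustness to every artifact of real genomes.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to exercise each
property with comfortable margins: tiny alphabets/lengths where an
exhaustive oracle is enumerable (≤ 6-residue pairs), 4–10 taxa for
additive-matrix checks, 30 sequences × 60 residues for motif recovery,
200 genes × 3 replicates for ΔΔCT calibration, and 10–20 seeded genomes
for duplication recovery. Every stochastic step flows from an explicit
seed through `numpy.random.default_rng`; pipeline runs with the same
config and seed produce bit-identical outputs, and the run manifest
records the seed, every threshold used, and input checksums.

## Known limitations

- The greedy splice inference is exact-match only; it is not a spliced
  aligner and will refuse CDS/genomic pairs with mismatches.
- Profile search is a position-profile approximation of a profile-HMM;
  scores are comparable within a run, not to HMMER bit scores.
- E-values reuse fixed gapped Karlin–Altschul parameters rather than
  estimating them per scoring system.
- The progressive aligner has fixed guide-tree and merge heuristics; for
  families with long, divergent indel histories a dedicated MSA tool will
  do better.
- Group extraction by longest-edge cutting matches clean group structure;
  on trees without clear long internal edges the partition is sensitive
  to branch-length noise.
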