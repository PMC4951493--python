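# Methods

## Scope and data model

The package operates on annotated genomes: contigs plus CDS features with
protein products. Coordinates are 0-based half-open internally; GFF3 I/O
converts from the format's 1-based inclusive convention. The translational
start site (TLS) of a gene is its first coding base in reading orientation
(`start` on +, `end − 1` on −). Promoter windows are defined relative to the
TLS, clamped at contig edges, and returned in reading orientation; the −
strand window mirrors the + strand definition, which is the only symmetric
choice. Proteins come from the GFF3 `translation` attribute when present,
otherwise from translating the CDS with the bacterial code (table 11);
internal stops and non-triplet CDS lengths are hard errors. Non-CDS features
are ignored and duplicate gene ids rejected.

Intergenic distance is `start(next) − end(prev)` over all adjacent gene pairs
on a contig, regardless of strand; overlaps give negative values that are
kept and included in the genome mean. Two promoter windows are used in
practice — `[−250, 0]` for motif discovery from ortholog promoters and
`(−250, +50)` for the regulon search — and both remain caller-configurable
(`upstream`, `downstream`).

## Sequence-information (Ri) site scoring

From `N` aligned sites, per-column frequencies are estimated with a
background-weighted pseudocount `c` (default 1):
`f(b,l) = (n(b,l) + c·q(b)) / (N + c)`. Column weights are
`Riw(b,l) = 2 + log2 f(b,l)` in bits and a site scores the sum of its
per-position weights. No small-sample correction is applied: the pseudocount
already regularises, and the correction term would shift all scores by a
constant per column without changing rankings. A motif is flagged palindromic
when its count matrix equals its own reverse complement exactly; palindromic
motifs score a site and its reverse complement identically, so scanning
reports each physical site once with a + strand representative. Ambiguous `N`
bases in scanned sequences score the column-average weight, keeping draft
assemblies scannable. The default scan threshold is 0 bits (any
positive-information position); the comparative matrix ignores the threshold
and records raw best scores.

In-silico saturation mutagenesis scores all `3W` single-nucleotide variants
of a site; `Δ(l,b) = Ri(site) − Ri(variant)`. A position is "tolerant" when
no substitution changes the score by more than a tolerance (default 1e-9
bits, i.e. exactly zero up to floating point); otherwise "essential". Under a
motif with perfectly uniform spacer columns, exactly the internal spacer
positions are tolerant. For that reason, the reference construction for this
analysis samples spacer columns with *balanced* composition (each column an
exact permutation of equal base counts): with finite unbalanced samples a
spacer column carries spurious information and no position is exactly
zero-change.

## De novo discovery (ZOOPS EM with palindromic constraint)

Each sequence carries at most one motif occurrence: with probability `γ` a
site is present, uniformly placed over the `m_s` possible starts, against a
0-order background estimated from the input. EM alternates posterior
occurrence responsibilities with expected-count re-estimation; a Dirichlet
pseudocount (0.5, background-weighted) makes it MAP-EM, and the penalised
objective is recorded per iteration and asserted non-decreasing. In
palindromic mode the expected count matrix is averaged with its reverse
complement after every M-step. This averaging is the exact maximiser of the
constrained objective provided the background is strand-symmetric, so the
background is symmetrised (`q_A = q_T`, `q_C = q_G`) in palindromic mode;
without that, the projection would not be the constrained M-step and
monotonicity could fail. EM runs on a single strand: for palindromic motifs
the two strands are equivalent, and the discovery use case here is
palindromic.

Width selection scans `w_min..w_max` (default 8–20). Significance is a
BIC-penalised log-likelihood ratio, `−2·LLR + k·ln(n_windows)` with
`k = 3·ceil(W/2) + 1` free parameters in palindromic mode (`3W + 1`
otherwise); lower is better and negative values beat the background-only
model (`significant`). Seeds per width (default 20) combine a deterministic
heuristic — occurrences of the most over-represented k-mers (k = min(5, W),
ratio of observed to background-expected counts), seeding the window both at
the k-mer and ending on it, since dyad arms sit at window edges — with random
restarts from the caller's RNG seed. All seeds get a 3-iteration trial EM;
the three most promising run to convergence (tolerance 1e-6 in the objective,
max 200 iterations). Identical inputs and seed give identical results.

## Orthology and the TF tree

Pairwise protein comparison is optimal local alignment (Smith–Waterman,
BLOSUM62, affine gaps: a length-g gap costs 11 + g), with expect values from
the Karlin–Altschul formula `E = K·m·n·exp(−λS)` using the standard gapped
constants λ = 0.267, K = 0.041 and the two sequence lengths as the search
space. Identity is matches over alignment columns. Orthologs between two
proteomes are unique reciprocal best hits by raw score at `E ≤ 1e-20`; ties
on the best score conservatively produce no pair. Cross-species groups are
anchored on a reference proteome (one group per reference gene, members =
RBH partners of the anchor; star topology, no transitive closure), mirroring
a reference-query comparative design. The TF tree is neighbour joining on
`1 − identity/100` distances from pairwise alignments rather than a multiple
alignment — a deliberate simplification that preserves the distance-based
clustering while avoiding an MSA engine; negative branch lengths are clamped
to zero and species enter in lexicographic order so ties resolve
deterministically.

## Operons, revision, and the regulon matrix

Directons are maximal runs of consecutive same-strand genes per contig.
Within a directon, adjacent genes merge into one operon when their intergenic
distance is *strictly* below the genome-wide mean intergenic distance; ties
split, strand switches always split, and a genome with fewer than two genes
has no defined mean, so every gene stands alone. The operon promoter is the
lead gene's window only; its best site (maximum score, ties resolved 5'-most)
is inherited by every member. Revision: a non-lead member whose own window
holds a hit scoring at least 0.75 × the maximum achievable motif score (the
threshold is a declared default — "high-scoring" is not quantified anywhere
authoritative) becomes the lead of a new operon; splits apply left to right,
one per operon per pass, repeated to fixpoint, after which promoters and best
hits are recomputed. Revision only splits; merging distant genes into an
operon on cross-species evidence is left to a manual override (pass
pre-merged operon lists), not an automatic rule.

The comparative matrix has reference-gene rows and species columns ordered by
TF-tree leaf order. A cell is ABSENT when the species lacks an RBH ortholog,
otherwise the best promoter score of the operon containing the ortholog,
min-max normalised over all non-absent cells of the whole analysis (the
analysis-wide maximum maps to 1, the minimum to 0; if all scores are equal
everything maps to 1). Species without a TF ortholog are excluded from the
tree and matrix and listed in `excluded_species`. For recovery scoring, a
(species, group) pair is called regulated when its raw best score reaches
0.5 × the maximum achievable motif score — again a declared default, chosen
to sit between the planted-site score distribution and the background
maximum under the default study conditions.

## Tandem sites and junction motifs

Tandem arrangements are ordered same-orientation site pairs in one promoter
with a gap of 0–10 bp (the secondary-score filter is off by default because
degenerate downstream sites are biologically meaningful). The junction is the
DNA spanning both sites. Junction matching uses guaranteed-match semantics:
an ambiguous subject position only matches a pattern position admitting every
base it could be, so a consensus-built junction (with `N` spacers) reports
only instances that exist for *every* concrete spacer realisation; on plain
DNA this is ordinary IUPAC matching. For arms `...GAACA` / `TGTTC...`, the
emergent GAAC-Nk-GTTC spacer covers the final A, the inter-site gap, and the
initial T, hence k = gap + 2; the canonical k = 4 instance appears at gap 2
only, which exhaustive enumeration over gaps 0–10 × k 0–12 confirms. Only the
combinatorial site-generation claim is implemented; evolutionary dynamics
(duplication, divergence, regulon takeover) are not simulated.

## Synthetic communities

The generator emulates the study inputs, not real genome complexity. Protein
families get random ancestors (uniform residues after an initial M, lengths
120–300) evolved along a species tree (random topology or user newick; each
branch applies per-site substitution with probability `1 − exp(−rate)`,
replacements drawn BLOSUM62-conditionally, default rate 0.15). Genomes place
operons — 8 regulated ones by default (lexA, recA, the imuA-imuB-dnaE2
cassette, splB, uvrA, uvrB, recQ, dinP) plus background operons with sizes
1–4 — in shuffled order on one contig, strands random. Intergenic gaps are
bimodal: within-operon gaps geometric with mean 20 bp; between-operon gaps a
minimum separation of 160 bp plus a geometric tail of mean 40 bp (overall
mean 200 bp). The separation floor is what makes the mean-distance operon
rule testable: a plain geometric would put roughly half of the between-operon
gaps below the genome mean and no threshold rule could recover boundaries.
Regulated lead genes get one site sampled column-wise from the motif model
(arms 1.95 bits/column by default, uniform spacers) placed uniformly so the
whole site lies in [−200, −20] of the TLS — inside both standard search
windows — with the preceding gap widened as needed to keep the site
intergenic; a fraction (default 0.25) also get a tandem secondary site at a
1–3 bp gap. One structural constraint keeps the ground truth well defined: a
regulated promoter gap is never shared head-to-head with another operon's
promoter, because a planted site in a shared gap genuinely falls inside the
neighbour's search window and would be scored a "false" positive that is in
fact a real site. Background DNA is i.i.d. with configurable GC (default
0.60).

What the generator does not model — repeats, HGT, rearrangement, gene
gain/loss beyond presence flags, codon-level evolution, σ-factor promoter
structure — is exactly what the pipeline under test also assumes away, so
passing tests demonstrate correctness of the implemented inference, not
robustness to real-genome confounders.

## Numerical choices and edge cases

Frequencies are kept strictly positive by pseudocounts, so logs are finite.
Consensus letters degenerate to IUPAC codes on frequency ties (tolerance
1e-9). EM γ is clipped to [1e-6, 1 − 1e-6]. Hit ties resolve 5'-most;
alignment ties resolve by sorted gene id; tree ties by lexicographic input
order. Degenerate inputs return empty results rather than errors where the
operation is well defined (no adjacent gene pairs, window shorter than the
motif, no hits above threshold); contract violations (unknown ids, invalid
characters, inconsistent lengths, impossible configurations) raise
`ValueError`/`KeyError` naming the offender.

## Problem sizes

Default test and reproduction sizes are desk-scale by design: 30 promoters ×
250 bp for discovery (full 8–20 width scan, 20 seeds, ≈7 s), 10 seeded
3-species communities of 30 genes for the end-to-end recovery suite (≈15 s),
100-fixture brute-force comparisons for scanning, operon prediction, and
alignment oracles. The full test suite runs in about a minute on one CPU.
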