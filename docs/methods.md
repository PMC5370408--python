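# Methods

This note records the models, rules and numerical choices behind
`aarscreen`, and what the synthetic-data tests do and do not demonstrate
about real data.

## tRNA model and cloverleaf folding

A fixed canonical cloverleaf consensus is bundled per isotype: 76 nt with a
5-nt type I variable loop, segmented as acceptor stem (7 bp), D-arm
(4 bp stem + 8 nt loop), anticodon arm (5 bp stem + 7 nt loop, anticodon at
canonical 34-36), variable region, T-arm (5 bp stem + 7 nt loop), the
unpaired discriminator N73 and the 3'-CCA. Type II tRNAs replace the
variable loop with a V-arm insert; a variable region of **>= 10 nt counts as
a V-arm** (the standard type I/type II convention — the literature contrasts
"V-arm" against V-arm-lacking tRNAs without giving a length, and 4-9 nt
variable loops are "absent").

Folding is an anchored template alignment with indels confined to the
variable region. Because every arm of the bundled template has fixed
length, the optimal such alignment has a closed form — variable-region
length = gene length − 71, with all other segment boundaries at fixed
offsets — and the implementation computes it directly rather than running
the degenerate dynamic program. A fold is accepted when the acceptor stem
shows **>= 6 of 7 Watson-Crick or G·U pairs** (tolerating a single mismatch,
as seen in real genes); otherwise a structured "unfoldable" result is
returned, never an exception. Consequences: the parser is exact and
deterministic for template-derived genes of any substitution divergence,
but it does not handle length variation in the D-loop or elsewhere, and it
is not a gene finder — inputs must already be annotated tRNA genes
(tRNAscan-SE territory is out of scope). Internally spans are 0-based
half-open; reports use canonical 1..76 numbering.

### Identity rule table

Tyr: G1-C72 with V-arm → bacterial; C1-G72 without V-arm →
archaeal/eukaryal; C1-G72 **with** V-arm → the chimeric combination
reported in CPR bacteria; all other combinations → ambiguous, with the
conflicting elements enumerated in the evidence. Trp: G73 → bacterial
(regardless of the 1-72 pair); A73 with G1-C72 → archaeal/eukaryal; else
ambiguous. The classifier is total over all 4x4x2 element combinations per
isotype (enumerated in a test). Duplicated tRNAs of one genome are all
reported; no deduplication is attempted.

## Synthetic-data generator

The generator is the ground-truth authority for every signal the pipeline
detects. Identity-element positions (1, 72, 73, anticodon) are never
mutated. Mutations elsewhere are uniform over {A,C,G,T} at the stated
per-site rate (capped at 0.3), with one deliberate exception: **acceptor-stem
pairs 2-7 mutate jointly** — a substitution on the 5' half rewrites the 3'
complement — so the stem stays paired and generated genes stay foldable at
any admissible rate. Independent per-base mutation would break the
>= 6/7-pair acceptor-stem requirement in ~10-17% of genes at rate 0.1,
which would contradict the generator's contract that folding recovers the
planted truth; compensatory (co-varying) stem substitution is also the
biologically typical pattern for stems.

Protein families evolve along a known tree: a random Yule-style topology
(or a user-fixed Newick), Poisson substitution counts per branch and a flat
20-letter replacement distribution. `subs_per_site` is the **expected
root-to-leaf divergence**; random branch lengths are drawn Exp(1) and
rescaled so the mean root-to-leaf path equals it (fixed-Newick branch
lengths are used as given). Planted motif columns (HIGH, KMSKS, the four
cysteines of the Fe-S motif) are never mutated. No JTT-style exchangeability
or rate heterogeneity is modelled: the generator's job is known topology
and protected signal, not realism. Passing tests therefore demonstrate
correctness of the inference machinery, not robustness to real-world
alignment error, compositional bias, codon usage or sequencing artefacts.

Contigs are assembled from feature templates (archaeal-identity
tRNA-Trp/tRNA-Tyr genes, lineage-ancestor CDSs reverse-translated with a
fixed codon table, arbitrary ORFs for trp-repressor/filler labels) with
seeded random intergenic spacers. Minus-strand layouts keep layout order as
transcription order. The lineage "ancestors" are deterministic synthetic
constructs — independent random sequences with the diagnostic motifs
planted (the TrpRS-A2 ancestor carries C-x22-C-x6-C-x2-C; the ORF1,
TrpRS-A1 and bacteria-type TrpRS ancestors are tryptophan-free, mirroring
the reported Trp-starvation signature) — and double as the labelled
reference set. An `orf1_no_motifs` template (motif positions ablated)
supports negative controls. The same locus grammar that detection uses is
applied to the *true* labels to derive truth operon calls, so
detection-vs-truth comparisons test label recovery from sequence, while a
separate brute-force window oracle tests the grammar itself.

## aaRS annotation

- **Motifs.** Degenerate class I patterns, configurable; defaults
  HIGH = [HNQ][ILVMAFG]G[HN], KMSKS = [KR][MLIVF]S[KS][SG] — the canonical
  class I consensus widened enough to catch "motif-like" ORF1 variants.
  Matching is greedy left-to-right and non-overlapping per motif. The Fe-S
  motif C-x22-C-x6-C-x2-C (34-residue span) reports all, including
  overlapping, placements. Only the sequence motif is modelled, not
  [4Fe-4S] chelation chemistry.
- **Similarity** is the BLOSUM62 *positives* fraction of a global affine
  alignment (open −11, extend −1), positives / alignment columns with
  terminal gaps excluded — matching BLASTp's "Positives", since the
  collection thresholds in this literature come from BLASTp. Identity is
  reported alongside; a full-length denominator (terminal gaps included) is
  available as an option. The pair is ordered canonically before alignment,
  so the measure is exactly symmetric. For unrelated random proteins this
  statistic measures ~0.25-0.32, comfortably below the 0.40 typing floor.
- **Lineage typing** is nearest-reference (not profile-HMM), reproducing
  the BLAST-similarity collection logic: nearest labelled reference wins if
  similarity >= threshold (default 0.40), ties break on reference id;
  otherwise `unassigned` — a query is never given a confident label below
  the floor. An optional flag additionally requires an Fe-S motif hit
  before a TrpRS-A2 call stands. TrpRS-A-like typing is purely
  reference-similarity based (no diagnostic indel positions are modelled).
- **Architecture.** Catalytic core = first HIGH hit through the first
  KMSKS hit downstream; ABD follows the core; a B2 domain is called when
  the pre-HIGH N-terminal region matches a user-supplied B2 reference at
  the similarity floor (with a >= 10-residue linker segment when present),
  and an S4-like domain when the C-terminal tail matches an S4 reference.
  Missing HIGH yields an empty core plus a warning, never an error.
- **Breakpoints.** The two genes are globally aligned; identity is computed
  in fixed windows (default 30 columns, step 10) along the alignment; a
  breakpoint is the midpoint between a >= `high_thr` plateau window and the
  next <= `low_thr` plateau window (defaults 0.9/0.5), mapped back to
  residue coordinates of the first sequence. Widening the (high, low) band
  can only reclassify windows to "mid", so the breakpoint count is
  monotone non-increasing in band width. This is a threshold-crossing
  detector for discrete junctions, not an HMM segmentation.

## Locus analysis

Operon patterns are evaluated in transcription order (5'→3' on the feature
strand; "headed by" = upstream). Strict patterns require adjacent members
with every internal gap <= `max_gap` (**default 150 nt** — compact-cluster
figures in this literature print no distance; 150 nt is the conventional
operon-gap heuristic, configurable): tRNA-Trp(A73)/ORF1/TrpRS-A1, the same
followed by a bacteria-type TrpRS, and the trp-repressor-headed variant.
Overlapping patterns are each reported. The archaeal TrpRS-A2/A-like
cluster requires only co-localisation — members within `cluster_gap`
(default 1000 nt) with intervening features allowed — since those loci are
described as linked clusters rather than strict operons. Trp-repressor
recognition is by annotation label (or user reference), not a bundled TrpR
model. An operon call never spans contigs or strands.

ORF1 candidates are the conjunction of three conditions: (a) position —
between a tRNA-Trp(A73) gene and a TrpRS-A-typed CDS (both within
`max_gap`), or co-localised with a TrpRS-A2/A-like gene within
`cluster_gap`; (b) no reference similarity — the classifier returned
`unassigned`; (c) motif content — at least one HIGH-like and one KMSKS-like
hit. Length bounds default to 120-450 residues (unstated in the source
literature; the bounds exclude trivial ORFs while keeping ORF1-scale
proteins). Each single-condition ablation flips the call (tested via
generator ablations).

## Phylogenetics

Tree inference is **distance-based NJ, not maximum likelihood**: the
family trees serve clade-grouping and congruence claims, and NJ + bootstrap
is deterministic, desk-scale and oracle-testable (NJ is guaranteed exact on
additive matrices, which the tests exploit). Externally computed ML trees
can be supplied as Newick wherever a tree is consumed, and reports carry
the method in their provenance. "Uniform rates" maps to the Poisson
correction d = −ln(1 − p) with p the mismatch fraction over mutually
ungapped columns (no gamma correction); pairs sharing < 20 ungapped columns
are an error, and p > 0.95 is capped with a warning. Q-matrix ties break on
the smallest (i, j) index pair; negative branch estimates are clamped to 0.

Progressive alignment uses 3-mer Jaccard distances, average-linkage guide
clustering with lexicographic tie-breaks, and vectorised profile-profile
Needleman-Wunsch (expected BLOSUM62 column score, linear gap −4).
Sequences are sorted by id first, so the result is input-order invariant.
Core trimming retains [first HIGH anchor column − `upstream_residues`
(default 13, clamped at column 1) .. ABD end]; the ABD end column is a
configured index or is mapped from a designated annotated reference row
(the anticodon-binding-domain boundary comes from known structures and
cannot be rediscovered from sequence alone) — an error asks for one of the
two. Columns > 50% gaps inside the window are dropped as non-conserved
insertions, but never the anchor columns. The upstream offset is a
parameter because "up to 13 residues" may have varied per family; 13 is
the default.

Bootstrap supports are the percentage of 100 (default) column-resampling
replicates containing each full-data bipartition; identical rows carry no
signal and yield an explicit unresolved star tree. Supports are invariant
to leaf input order (canonical bipartition hashing).

### Congruence test

Two gene trees (paired by genome id) are restricted to their shared leaves
(>= 4 required); the statistic is the Robinson-Foulds bipartition distance;
the null permutes the leaf labels of the second tree (default 999
permutations, seed recorded); p = (1 + #{permuted RF <= observed}) /
(n_perm + 1). Normalised RF divides by 2(n−3).

Calibration caveat, measured rather than assumed: because RF is discrete
and concentrates near its maximum for unrelated trees, the inclusive-tie
permutation p is **valid but conservative**. On independent random
12-leaf topologies the empirical type-I error at α = 0.05 is ≈ 2-3%
(large-replicate estimate 2.3% ± 0.3), inside a ±3-percentage-point band
around nominal but near its lower edge; at 16 leaves it drops to ≈ 1.6%,
outside that band. The p-value distribution under the null is therefore
*not* uniform — it is stochastically larger — and for trees with symmetric
shapes even identical trees cannot reach the minimal p, since symmetric
relabellings reproduce RF = 0. Co-evolved pairs (shared topology,
12 leaves, moderate divergence) are detected at p <= 0.01 with 999
permutations.

Neighbor-joining vs least-squares agreement on 4-taxon problems is
evaluated on *noisy-additive* matrices (a random 4-taxon tree, internal
branch 0.1-0.6, Gaussian perturbation sd 0.03): for fully arbitrary
non-tree-like matrices the two criteria genuinely differ and agreement is
near chance, so tree-derived distances with perturbation below the internal
branch are the meaningful regime for that check.

## Pipeline and IO

Stages run cloverleaf → aaRS typing → locus analysis → optional phylogeny;
record-level failures become warnings and skips, file-level problems are
fatal before any stage runs. Reports carry a provenance block (config
hash — output directory excluded, tool version, seeds); re-running a config
on the same inputs is byte-identical. All randomness is seeded explicitly;
no global RNG state is used anywhere. GFF3 is 1-based inclusive with `ID=`
attributes; Newick supports live in internal-node labels; the truth table
serialises losslessly to TSV (JSON-encoded cells) and JSON.

## Problem sizes

Default verification sizes: 1000 tRNAs per identity type (rate 0) plus
1000 at rate 0.1; 1000 random 300-mers for scanner/oracle equivalence;
200 synthetic contigs for operon precision/recall; 200 random trees
(n <= 12) for NJ recovery and 100 4-taxon trials; 12-leaf families with
300-residue roots and 999 permutations for congruence, with 500 null
trials; 100 planted domain-swap constructions. These sizes give
sub-percent Monte-Carlo resolution on the reported rates while keeping the
full verification run in the tens of seconds.

## Known limitations

- The cloverleaf parser assumes template-conformant arm lengths; real genes
  with D-loop length variation or introns will fold incorrectly or report
  unfoldable.
- Nearest-reference typing inherits the reference set's coverage; a
  lineage absent from the references can only ever be `unassigned`.
- NJ topologies are not ML topologies; published figure topologies are not
  reproduced (they depend on external sequence sets and ML software).
- The congruence p-value is conservative (above); borderline co-evolution
  signals may be missed.
- Secondary/tertiary structure prediction, live database searches,
  tRNA gene finding and LGT direction inference are out of scope.
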