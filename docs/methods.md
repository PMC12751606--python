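# Methods

## Scope and model

`ppinet` infers intra-genome protein–protein interaction networks from
multi-genome protein FASTA input using two genomic-context signals:
conserved phylogenetic profiles and conserved gene neighborhoods.  The
package's premise is alignment-free similarity: instead of sequence
alignment, each protein is reduced to a 60-value propensity descriptor
and pairs are compared in descriptor space, either by threshold matching
(Features mode) or by a trained random-forest classifier (ML mode).

Gene order is defined as record order within each genome's FASTA file.
This is a modeling assumption, not a file-format guarantee: neighborhood
inference is only meaningful when the input files list proteins in
chromosomal order (as proteome exports from annotated genomes normally
do).

## The propensity descriptor

The bundled `propensity.dat` carries 10 scales over the 20 standard
amino acids: four class indicators (BASIC, ACID, POLAR, NONPOLAR), the
average residue mass (MASS) and free amino-acid molecular weight
(MASSMR), and four hydropathy-type AAindex scales (PARJ860101,
JOND750101, EISD840101, JURD980101).  The exact numeric values are
configuration — any complete 10-scale table produces a valid descriptor,
and a user table can be supplied everywhere a default is used.

For each scale the descriptor stores raw (not length-normalized) sums of
per-residue values over the whole sequence and over the start, middle
and end regions; region boundaries are ⌊n/3⌋ residues for start and end
with the remainder assigned to the middle.  Raw sums were chosen because
the Features-mode rule compares coordinates with an absolute unit
tolerance, which only discriminates on un-normalized sums; whole-sequence
sums therefore satisfy the exact additivity invariant
`whole = start + middle + end`.  The 20 count features are the standard
amino-acid counts in alphabetical order.  Non-standard letters
(B, J, O, U, X, Z) are accepted in input sequences but contribute zero to
every scale sum and are excluded from the counts (logged as a warning);
any other letter is an error.  The feature layout is frozen and
versioned (`propensity-60/v1`); serialized models record the version and
prediction refuses a mismatch.

## Pair similarity

*Features mode* declares two proteins similar when at least
`min_matches` (default 25) of the 60 coordinates differ by at most
`tolerance` (default 1 unit; 2 is the documented alternative).  The rule
is symmetric and monotone: lowering `min_matches` or raising `tolerance`
never turns a similar pair dissimilar.

*ML mode* encodes a pair as the element-wise absolute difference of the
two descriptors — symmetric by construction and aligned with the
per-coordinate semantics of Features mode — and classifies it with a
random forest configured as: 500 trees, maximum depth 30, 10 candidate
features per split, full bootstrap, minimum leaf size 1.  Training
tables list all negatives before all positives and downsample negatives
(seeded, without replacement) to a 3:1 negative:positive ratio by
default.  The decision threshold is 0.5 (majority vote).  The depth
default is recorded literally as 30 even though the "half the features
plus one" rule would give 31; both are configurable.

Labels for real data are expected from an external source (e.g. an
alignment run done elsewhere) as a labeled pair table; the package
implements no alignment engine.  Synthetic data is labeled from
generator ground truth using the >65% identity convention.

## Phylogenetic profiles

A protein's profile is the boolean vector "a similar protein exists in
genome g" over the fixed input genome order, with the own-genome bit
always true (an equivalent convention to dropping it, fixed for
reproducibility).  Proteins of the same genome are linked when their
profiles differ in at most `diff_tolerated` positions (default 0).
Profiles true only in the protein's own genome are uninformative and
generate no edges.  Identical-profile groups are completed as cliques;
the cross-group tolerance rule links member pairs of groups within the
Hamming bound, so the edge set grows monotonically with the tolerance.

The `complete` flag mirrors the unfiltered default operating mode of the
profiling method; filtered variants are not implemented, and setting
`complete=False` currently logs a warning and runs unfiltered.

## Gene neighborhoods

The neighborhood rule is a reconstruction from the parameter semantics
(`w1`, window size, default 10; `cw1`, conservation quota, default 4;
fixed or dynamic expansion) and is isolated behind its own function so
the rule can be swapped without touching the rest of the pipeline.  For
a target gene *g*: anchor a `w1`-window on *g* (truncated at the ends of
the gene list; no circular wrap by default).  For every other genome and
every gene *g′* there similar to *g*, count the distinct genes of *g*'s
window that have a similar counterpart inside *g′*'s window; if at least
`cw1` do, link *g* to each conserved partner.  Dynamic expansion grows
the window from `dynamic_start` (default 3) until the quota is first
met and then keeps expanding while it still holds, up to `w1`, keeping
the largest passing window — growth past the first success is required
because a 3-gene window cannot contain `cw1 = 4` candidates.

## RIS

Identical-profile groups larger than the trigger N (default 100,
strictly "more than") are sampled instead of completed: shuffle the
members with the seeded generator; partition the shuffled list
round-robin into k = max(2, ⌊0.9·x⌋) disjoint sublists; draw 2 connector
members uniformly and append them to every sublist; emit the union of
within-sublist cliques, deduplicated.  Round-robin partitioning bounds
the worst-case sublist size; the shuffle already randomizes membership.
The output is always a strict subset of the complete pair set for
x > N, covers every member, and is identical for identical seeds.
Members are treated exchangeably, so the expected degree reduction is
homogeneous across the group — the property that preserves hub rankings.

The source description of the sublist geometry is contradictory: the
"number of sublists = 90% of group size" reading is adopted because the
alternative ("each sublist about half the list") regenerates nearly all
edges and defeats the stated reduction purpose.  The fraction and the
connector count are configuration.

## Centrality and stability statistics

Degree, unnormalized betweenness (Top-N ranking is invariant to the
normalization choice), and bridging centrality
`betweenness(v) · (1/deg v)/Σ_{u∈N(v)} (1/deg u)` are supported; ties in
Top-N selection break by node id ascending so replicate rankings are
comparable.

Agreement across R replicates is summarized by: MGP = 100·Σfᵢ²/Σfᵢ over
presence frequencies fᵢ of Top-N nodes (a reconstruction of the named
weighted-presence metric: weighted by frequency of appearance,
down-weights sporadic nodes, equals 100 iff fully consistent); mean
pairwise Jaccard of Top-N sets; two-category Fleiss' κ with replicates
as raters and the union of all replicate node sets as the item universe
(so non-selection is informative; degenerate all-equal tables return 1);
Kendall ratio positive (concordant/comparable ordered pairs over shared
nodes, ties excluded from the denominator, averaged over replicate
pairs); and the maximum pairwise two-sample KS distance of the
centrality-value distributions (mean-pairwise available).  Replicate
seeds derive deterministically from the master seed and are recorded in
every report.

The full protocol grid is 2 modes × 5 file counts × 6 Top-N values × 3
metrics = 180 configurations at R = 50 replicates; tests and the smoke
path exercise the identical code at R = 2–3 on reduced grids, purely as
the package's own default experiment size.

## Synthetic data

The generator emulates exactly the structure the pipeline consumes:
protein families with one ortholog per member genome, per-family
presence patterns (controlling profile-group sizes, including groups
above the RIS trigger), conserved gene order with optional seeded
adjacent-swap shuffling, and uniform background residue composition by
default.  Orthologs derive from a family ancestor by independent
per-site replacement with a composition-drawn residue (no indels), at
rate 1 − √t for target pairwise identity t, so measured identity is the
fraction of equal sites and the >65% label is analytically controllable.
Defaults — 5 genomes, 200 families, 150-residue proteins, 80% family
identity — are one fixed choice of realistic desk-scale conditions.

What the generator does **not** emulate: insertions/deletions, length
variation within families, paralogy (multiple family members per
genome), compositional bias across genomes, operon-scale rearrangement,
and realistic substitution matrices.  Passing tests therefore
demonstrate internal correctness and the method's behavior under its own
assumptions, not performance on real proteomes.

## Numerical and degenerate-case choices

* Confusion-matrix rates: sensitivity tp/(tp+fn), specificity
  tn/(tn+fp), F1 = 2tp/(2tp+fp+fn); zero denominators yield NaN with an
  explicit undefined flag; display rounding is 4 decimals.
* Two empty Top-N sets have Jaccard 1 (flagged degenerate); Fleiss' κ
  returns 1 when expected agreement is already perfect; replicate pairs
  sharing fewer than two ranked nodes are skipped by the Kendall ratio.
* Edge normalization: canonical undirected keys are sorted endpoint
  tuples; self-loops are rejected.  DOT output sorts edges canonically,
  so equal networks serialize byte-identically.
* The edge-list comparison reports both the record-level overlap (which
  double-counts a reference stored in both orientations — kept to
  reproduce the published self-comparison arithmetic of 0.50/2.00) and
  the normalized undirected overlap, which is the recommended reading.
* Isolated proteins are excluded from networks and DOT node lists by
  default (published per-genome node counts are below proteome sizes),
  but can be included explicitly.
* Parallel execution is intentionally absent: results are specified as a
  pure function of (inputs, configuration, master seed), which is the
  portable form of the result-invariance contract; all orderings that
  feed random draws are explicitly sorted.

## Known limitations

* The propensity table values, the pair encoding, the MGP and adapted
  Fleiss formulas, and the neighborhood mechanics are reconstructions of
  components whose exact definitions are not public; each is isolated
  behind its interface and documented as such.  Numeric agreement with
  any particular external implementation's features or model is
  therefore not claimable.
* Gene-fusion evidence, inter-genome edges, per-edge confidence scores,
  database access, and plotting are out of scope.
* Features mode is O(P²) descriptor comparisons over all protein pairs
  (vectorized in chunks); ML mode additionally pays one forest
  prediction per pair block.  Desk-scale inputs (a few thousand
  proteins) run in seconds to minutes; whole-pangenome runs were not a
  design target of this implementation.
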