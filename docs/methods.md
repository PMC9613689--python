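# Methods

This note documents the models and procedures implemented in `parawasp`,
the conventions and defaults each stage uses, what the synthetic-data
generators emulate, and the design choices made where more than one
reasonable convention exists.

## LTR insertion dating

The two long terminal repeats of a retrotransposon are identical on
insertion and diverge neutrally afterwards, so their Kimura two-parameter
distance K dates the insertion as T = K / 2r, with r the lineage
substitution rate in substitutions/site/My. K2P separates the transition
proportion P from the transversion proportion Q over *comparable* columns:
columns containing a gap or N in either sequence are excluded (pairwise
deletion, the standard convention). Pairs for which 1−2P−Q ≤ 0 or
1−2Q ≤ 0 are saturated: they are flagged and excluded from histograms
rather than clamped, to avoid fabricating finite ages for undatable
elements.

r is genuinely a user input: it varies several-fold between insect
lineages and must come from an external dated phylogeny. The fallback
default (0.0029 subs/site/My, a generic insect nuclear rate) triggers a
warning; relative ages are meaningful under any fixed r, absolute ages are
not unless r is lineage-calibrated.

The built-in pairwise aligner (match 1, mismatch −1, gap −2) is a
convenience for toy inputs; production inputs should arrive pre-aligned.

### Generator

`gen_ltr_pairs` evolves one ancestral sequence along two independent
branches of r·T expected substitutions/site under the two-rate
(transition/transversion, ratio kappa, default 2) process whose matched
estimator is exactly K2P — estimator consistency is the test surface, so
the generating process and the estimator share a model by construction.
Branch substitution probabilities use the closed-form K80 transition
matrix, not per-site Poisson counts, so multiple hits are modelled.

## piRNA profiling and Ping-Pong scoring

Reads of 24–35 nt not flagged as structural ncRNA are piRNA candidates.
The Ping-Pong amplification loop produces sense/antisense piRNA pairs
whose 5′ ends overlap by exactly 10 nt; the implemented overlap convention
is o = q − p + 1 for a plus-strand 5′ end at p and a minus-strand 5′ end
at q (both in plus-strand coordinates), which places the canonical pair
exactly at o = 10. The off-by-one alternative (o = q − p) was rejected:
under it the canonical pair lands at bin 9 and the 10-nt signature of the
field's convention would be misaligned.

The Ping-Pong score is the Z of N₁₀ against all other bins (default
o ∈ {0..9, 11..30}) using the sample (n−1) standard deviation; a
zero-variance background returns an undefined sentinel rather than ±inf.
Pair counting at each (p, q) uses min of the two 5′-position
multiplicities, avoiding the quadratic double-counting of all-vs-all pair
enumeration; a collapse-to-unique-positions mode is provided for
sensitivity analysis, since upstream protocols differ in whether
multiplicity is meaningful after deduplication.

Reads are assigned to TE classes by ≥ 1 bp interval overlap, the class
with the longest total overlap winning (lexicographic tie-break for
determinism). The family-level report correlates per-family Z with median
family insertion age (Spearman); it is skipped below three families.

### Generator

`gen_small_rna` plants a configurable fraction of reads as exact-10-nt
overlap pairs on TE consensus sequences and places the rest uniformly on
random strands. The 1U and 10A biases are applied exactly (the biased
base with the stated probability, otherwise uniform over the other three)
to all reads, so measured frequencies equal the configured proportions in
expectation and saturate at 1.0. Sequencing error, quality scores and the
read-mapping step itself are not simulated — hits are emitted directly —
so the tests establish the correctness of the counting and scoring
conventions, not robustness to mapping artefacts.

Null calibration: with no planted pairs, the 10-nt bin is exchangeable
with its background up to edge effects, and |Z| < 3 holds in ≈ 99% of
seeded runs (the criterion requires ≥ 95%).

## Venom-gene calling

N90 is the expression value at which the cumulative TPM of
descending-sorted venom-gland genes reaches 90% of the sample total — in
a secretory tissue where ~2% of genes carry 90% of the transcriptome,
this isolates the specialised high end. A gene is called venom iff its
venom-gland TPM is *strictly* greater than N90 ("higher than" is read
literally; the TPM = N90 boundary case is excluded) and at least three
fully matched proteomic peptides support it. Replicates are averaged
(arithmetic mean) per stage label before thresholding. The N90 rule is
scale-free: multiplying all TPMs by a constant leaves calls unchanged.

Venom-gland specificity (VG TPM over the maximum non-VG TPM plus a 0.01
pseudocount) is a descriptive output only and never gates calls, because
no principled formula for "specialisation" is fixed by the calling rule
itself.

## Venom orthogroup evolution

Orthogroups are compared between the two focal species: shared venom OGs,
species-specific venom OGs, and the strictly conserved subset (identical
venom-gene copy number in both). OGs restricted to the focal clade or
with fewer than five members are dropped before tree-based analysis —
both give ambiguous gene trees.

**Recruitment dating.** Presence/absence of an OG over the dated species
tree is reconstructed by Wagner parsimony with equal gain/loss costs
(Sankoff dynamic programming). The recruitment age is the oldest node
reconstructed as present; state ties during the top-down pass resolve
toward presence, which implements a gain-early preference (shared
presence is read as ancestral rather than convergent). The
implementation is verified against exhaustive enumeration of all internal
labelings on random ≤ 10-leaf trees.

A topology caveat documented here because it bounds recovery: when the
gain node's immediate descendant lineages are cherries, a single tip loss
produces a cost tie that the gain-early preference resolves correctly;
but when the gain clade has a basal singleton lineage, losing that one
tip makes the tipward gain strictly cheaper and no tie-break can recover
the truth. Planted-gain recovery at 10% loss is therefore ≈ 98% for
cherry-fronted gain nodes and ≈ 1 − loss_prob for basal-singleton clades
— a property of parsimony itself, not of the implementation.

**Origin classification.** Gene-tree internal nodes are annotated
duplication/speciation by the species-overlap rule (duplication iff the
child clades' species sets intersect), which mechanises manual tree
inspection and agrees with LCA reconciliation on species-tree-consistent
topologies (tested against a reconciliation oracle). For each venom
leaf, the most recent duplication on its root path decides the model:
none → single-copy co-option (if the OG is single-copy in every species);
span including non-chalcid species → ancient-duplication co-option; span
inside Chalcidoidea but beyond *Anastatus* → chalcid-duplication
co-option; span within *Anastatus* with a non-venom paralog →
duplication-neofunctionalization. Anything else is left unclassified
rather than forced — reported origin-model fractions need not sum to 1.
Branch support values are ignored by default (thresholds configurable):
no principled cutoff exists for overruling a topology that was accepted
upstream.

The default dated backbone is a 20-taxon tree (19 hymenopterans + a
dipteran outgroup) with the focal pair diverging at 3 My, their family
joining Pteromalidae at 78 My ("EPA") and Chalcidoidea at 105 My ("CA");
ages follow published calibration ranges for the named clades and
plausible interpolations elsewhere.

## Regulatory divergence and NRERs

Ortholog expression divergence is Spearman's rank correlation over
matched stage vectors (≥ 4 stages; mid-ranked ties; constant vectors give
an undefined sentinel). The TE-insertion effect is a two-sided Wilcoxon
rank-sum test between correlation coefficients of ortholog pairs with and
without a recent nearby insertion — exact null distribution when
min(n, m) ≤ 8 without ties, tie-corrected normal approximation without
continuity correction otherwise (verified against exhaustive enumeration
for all group sizes with n + m ≤ 10).

NRER detection scores every reference base of a regulatory region
(1 kb strand-aware flanks and introns) as identical or divergent
(mismatch, aligned-to-gap, or unaligned — absence of alignment is
evidence of divergence here, since the genomes are close enough that
orthologous sequence aligns). Candidate runs are seeded where the
20-bp-window identity drops to ≤ 0.5, trimmed to their outermost
divergent bases (which restores exact boundaries on clean signal), merged
across < 10 bp gaps, and reported when strictly longer than 60 bp. The
60 bp minimum is the biologically motivated threshold; window, identity
and merge-gap defaults are calibration knobs for the "obvious divergence"
judgement and are exposed in the API. Output is invariant to how the
aligner split blocks at non-NRER positions. A region with no coverage at
all is returned whole, flagged `no_coverage`, rather than silently
treated as one giant NRER.

An NRER is attributed to a recent TE insertion when ≥ 50% of its length
overlaps the supplied recent-TE intervals. Expression shifts between the
species' venom glands are classed by fold change FC = (max + 0.1) /
(min + 0.1) — the 0.1 pseudocount keeps near-zero TPMs finite — with
FC > 6 a large shift and FC < 1.25 stable. Enrichment of NRERs in shifted
vs stable genes is Pearson's chi-square (1 df) without continuity
correction on gene-level counts (a gene counts once however many NRERs it
carries); Yates correction is available behind a flag.

### Generator

`gen_alignment_blocks` tiles the reference with identical two-species
blocks and leaves planted intervals uncovered — the footprint a TE
insertion in one genome leaves in a pairwise alignment. It does not
simulate point-divergent (aligned but mismatching) NRERs or alignment
noise, so detection tests certify the coordinate bookkeeping and
threshold logic, not the behaviour of the identity window under
borderline divergence.

## Coexpression networks and the VRM

The network is the unsigned weighted construction: adjacency
a_ij = |cor(x_i, x_j)|^β with soft power β = 4, zero diagonal, and
topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij) /
(min(k_i, k_j) + 1 − a_ij). Genes expressed nowhere are removed;
constant genes are dropped with a warning.

Modules come from average-linkage clustering of 1 − TOM. The dynamic
hybrid tree cut of the reference implementation is deliberately not
reproduced (it is under-specified for reimplementation); the static
replacement cuts at the largest gap between consecutive merge heights
within the top decile of merges. The gap separates between-module joins
from within-module joins on modular data, and the two failure directions
are asymmetric: an over-split is repaired by the subsequent
eigengene-merge step, an under-cut is not, so the cut is biased low.
(A fixed-quantile cut was considered and rejected: it cannot recover k
modules when k − 1 between-module merges exceed its tail.) Clusters
under 30 genes are unassigned ("grey"); modules whose eigengenes
correlate at ≥ 0.75 (merge threshold 0.25 on the dissimilarity scale)
are merged iteratively, most similar pair first.

A module eigengene is PC1 of the gene-standardised module submatrix,
its sign fixed by non-negative correlation with the mean module profile;
kME is a gene's Pearson correlation with an eigengene (signed; shift and
connectivity analyses use |kME|, and grey genes are excluded from shift
statistics). The VRM is the module capturing the most venom genes
(lexicographic tie-break, logged). The dispersal check rebuilds the
network without venom-gland samples and reports whether any module still
captures ≥ 50% (configurable) of venom genes — a transparent descriptive
criterion in place of a module-preservation statistic, whose choice the
analysis it supports does not pin down. Cross-species analysis classes
each one-to-one ortholog in the VRM as module-conserved or shifted,
tests venom vs non-venom shift counts by chi-square, and compares |kME|
of shared-OG vs species-specific-OG members by rank-sum.

### Generator

`gen_expression_pair` draws each gene's mean profile as
λ·factor + (1−λ)·private, with nine stage/tissue labels (three
replicates each by default), five background stage programs and one
venom-gland-exclusive factor, per-gene private profiles shared by the
ortholog pair, and heteroscedastic noise (sd = noise_sd·√(mean+1) TPM).
The mixing weight λ is the gene's true connectivity, so kME recovers it
and "periphery" is well-defined. Defaults — a 60-gene venom module (40%
venom-flagged, λ ∈ [0.3, 0.95]), 6 venom expression shifts, 18 module
shifts planted in the lowest-λ periphery — are scaled-down analogues of
a ~600-gene VRM with ~40% one-to-one ortholog turnover concentrated in
peripheral non-venom genes; a guard keeps the species-B module above the
30-gene caller minimum. Venom-flagged genes receive ≥ 3 synthetic
peptides, so the venom caller's recall/precision on this generator tests
the N90 + peptide rule, not peptide-evidence noise. What passing tests
do *not* show: robustness to normalisation artefacts, batch effects, or
modules violating the single-factor mixture shape.

## Numerical conventions

- BED-style intervals are 0-based half-open throughout; GFF3 input is
  converted on read. MAF reference rows must be plus-strand.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is byte-deterministic given its seed and configuration.
- Undefined statistics (zero-variance backgrounds, constant vectors,
  zero intact-LTR counts) return explicit sentinels (`None`/`nan`), never
  clamped or infinite numbers.
- The solo:intact ratio with zero intact elements is undefined (`None`),
  not infinity.

## Problem sizes

Tests and the acceptance script run at desk scale: 500 LTR pairs,
5,000-read small-RNA populations (100 seeded null runs), 500–800-gene
expression matrices with 27 samples, 200 random trees for the parsimony
oracle and 50 gene trees per origin scenario. These sizes hold estimator
standard errors comfortably inside the stated tolerances while keeping
the full suite in the tens of seconds.

## Known limitations

- Absolute LTR ages require a user-supplied lineage rate; the default is
  generic and flagged.
- The piRNA stage consumes mapping records; multi-mapping resolution
  beyond one-random-best-hit reporting is out of scope.
- NRER identity/window/merge defaults encode an "obvious divergence"
  judgement and should be recalibrated for genome pairs at other
  divergence scales.
- Wagner-parsimony dating inherits parsimony's basal-singleton blind spot
  (see above).
- The module detector is a deliberately simplified static-cut
  approximation of dynamic tree cutting; on real data the module count
  near the cut boundary may differ from the reference implementation's.
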