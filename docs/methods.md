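# Methods

This note documents the models, conventions and numerical choices behind
`nrbgrn`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Quantification

Counts are recovered from per-transcript nucleotide coverage as
`reads = coverage · transcript_length / read_length` with a default read
length of 151 bp, rounded **half-up** to integers. The rounding rule is
arbitrary but must be fixed for reproducibility; half-up was chosen because
it is exact on the `.5` grid that the formula produces for even-length
transcripts. When several transcripts exist per gene, the longest
transcript's length is used — a deterministic rule chosen over
expression-weighted alternatives that would make lengths depend on the
sample set.

TPM is the usual length-normalised measure; every sample column sums to
10^6 (guaranteed to ~1e-15 relative in the implementation, asserted at
1e-6). The expression floor is a **strict** inequality, TPM > 5 in at
least one sample of the scope, so a gene sitting exactly at 5 everywhere is
excluded.

The MAD gene selector (for embedding-style visualisation) z-scales each
gene across samples (ddof = 1, matching R's `scale`) and ranks genes by the
median absolute deviation of the scaled profile, ties broken
lexicographically by gene ID. Constant genes cannot be scaled; they keep
their raw (zero) MAD and a warning is logged.

## Differential expression

The two-stage design reflects the biology: stage one (pooled NRB pulvinus
vs pooled internode rind, up-regulated only) finds NRB-enriched genes;
stage two (all pairwise phytomer-stage contrasts, two-sided) finds genes
that move during development; their intersection is the NRB-development
set used for network inference.

The per-gene test is **Welch's unequal-variance t on log2(TPM+1)**. This is
a deliberate substitution for count-model packages with shrinkage
estimators: it is closed-form, assumption-light and deterministic, and in
this design the binding constraint is the 5-fold-change filter, not the
p-value — at 45-vs-15 samples (stage one) any gene passing the fold filter
is overwhelmingly significant. Degenerate genes (zero variance in both
groups) get p = 1 when the means agree and p = 0 otherwise.

Fold changes are ratios of group means of TPM with a **pseudocount of 1
TPM**, direction-restricted (up in NRB) in stage one and absolute in stage
two. Benjamini–Hochberg is applied within each contrast separately, not
across the family of 105 pairwise stage contrasts; joint control across
the family would be stricter and is left configurable by calling
`bh_adjust` over concatenated p-vectors if desired.

## Expression cohorts

Genes are summarised as the median TPM per stage across replicates —
medians, not means, so a single aberrant replicate cannot move the profile
— then z-scaled per gene (constant genes are excluded with a warning). The
number of cohorts is chosen by the within-sum-of-squares elbow, formalised
as the k in 2..k_max−1 maximising the second difference
WSS(k−1) − 2·WSS(k) + WSS(k+1) of the best-of-25-restarts k-means curve.
For equally sized, mutually equidistant clusters this statistic provably
peaks at the true k (the between-cluster contributions telescope); for
clusters at very unequal separations it can fire at the first large merge
instead, which is a property of the elbow heuristic itself, not of the
implementation. K-means is Lloyd's algorithm with k-means++ initialisation
and 25 restarts (scikit-learn), fixed seed; labels are renumbered by
descending cluster size with ties broken by the smallest member gene ID so
output labels are deterministic.

## Co-expression network

The network is built on the **NRB development samples only** (the stage
series); internode controls are excluded because a shared tissue contrast
would otherwise dominate every pairwise correlation in the DE set. The
pipeline correlates log2(TPM+1); the adjacency function itself is
transform-agnostic.

Adjacency is unsigned, `a_ij = |cor|^β`, with the correlation sign kept
separately so downstream edges can be labelled activating (+) or
repressing (−). β is selected by the scale-free criterion: connectivities
`k_i = Σ_j a_ij` are binned into 10 equal-width bins of log10 k, the log
per-bin frequency is regressed on the log per-bin mean connectivity, R² is
signed by the negated slope (so only decreasing fits count), and the power
whose signed R² is closest to 0.9 wins, ties to the smaller power.
Degenerate connectivity distributions (all equal) skip the power with a
warning.

The topological overlap matrix follows the standard formula
`ω_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
`ℓ_ij = Σ_{u≠i,j} a_iu a_uj`; with a zero diagonal this is a single matrix
product. The result is symmetrised against round-off and clipped to
[0, 1]; ω ≥ a is *not* an invariant (false in general) and is not assumed.

**Mutual rank** is computed after restriction to the DE gene set. Within
the subset, gene i ranks its N = |subset|−1 partners by descending weight
(rank 1 strongest, ties get the mean rank), converted to a percentile
`r_i(j) = (N − rank_i(j) + 1)/N`, and `MR(i,j) = sqrt(r_i(j)·r_j(i))`,
so MR ∈ (0, 1] with 1 = mutually top-ranked. This normalisation is chosen
because the retention rule "mutual rank > 0.98" is only coherent for a
high-is-good statistic; with ~200 DE genes it keeps, per gene, roughly the
top 4–9 partners depending on reciprocity. MR is invariant under any
strictly monotone transformation of the weights. The classical low-is-good
geometric mean of the two raw ranks is available via
`mutual_rank(..., convention="raw")` for users who prefer that scale; the
pipeline and its thresholds use the percentile form throughout.

## Promoter scanning

Promoters span 1 kb upstream of the TSS, strand-aware: `[TSS−1000, TSS)` on
the forward strand for + genes, `(TSS, TSS+1000]` reverse-complemented for
− genes, clipped and flagged at contig edges. All coordinates are 0-based
half-open internally; BED6 is native and GFF3 (1-based inclusive) is
converted on input.

PWMs are probability matrices scored by log2-odds against the background
with pseudocount regularisation:
`score = Σ_pos log2((p + pc·bg)/((1+pc)·bg))`, pc = 0.1 by default. A hit's
relative score rescales the log-odds between the minimum and maximum
attainable for the matrix, so the consensus word scores exactly 1.0.
Windows containing N score −∞ (conservative: an ambiguous base never
supports a binding call). Both strands are scanned; a − strand hit at
offset o means the reverse-complement motif matches the given sequence at
o, which keeps all offsets in promoter coordinates. The default relative
score threshold is 0.85, a common operating point for PWM matching; it is
a flag everywhere it appears.

## GRN assembly

Edges among DE genes survive only with TF support: (i, j) is kept iff i is
a TF with ≥1 hit in j's promoter or vice versa; both directions are
recorded when both genes are TFs. Retention thresholds are strict:
weight > 0.1 AND mutual rank > 0.98. Genes whose every edge is pruned
simply disappear from the edge roster. Ego (first-neighbor) modules follow
the activation convention: "activated by the seed" requires seed→partner
support and a positive correlation sign; "activators of the seed" requires
partner→seed support and positive sign; negative-sign edges never enter
activator modules.

## Synthetic data generator

The generator emulates the study design the pipeline expects, with every
output a deterministic function of one seed:

- **Design.** 15 NRB stages (phytomers 7–21) × 3 replicates plus 5
  internode control groups × 3 replicates; 2,000 genes.
- **Counts.** Negative binomial via gamma–Poisson, variance μ + φμ² with
  φ = 0.02 by default (biological replicates of an inbred line). Library
  sizes are log-normal around 2×10^6 with 8% log-sd. Planted effects
  multiply a **fixed reference composition**, so the class-mean count ratio
  of a planted tissue-DE gene equals `de_fold` exactly while total library
  mass differs between classes as it does in real libraries; on the TPM
  scale the fold change is compressed by the total-mass ratio (≈1.2 at the
  defaults), which stays well above the 5-fold filter for `de_fold` = 8.
- **DE structure.** Tissue-DE and stage-DE rosters are drawn from one
  ordered candidate list (regulon genes first), so the two sets overlap
  heavily — NRB developmental genes are both NRB-enriched and
  stage-dynamic, and the two-stage intersection is only meaningful with
  substantial overlap. Stage-DE genes get smooth multiplicative stage
  curves with max/min ratio exactly `de_fold`, arithmetic mean 1 across
  stages (so stage curves do not masquerade as tissue effects).
- **Regulons.** Co-expression modules are star-shaped: the TF carries the
  module's latent curve; each target adds a small smooth individual
  deviation (amplitude 0.15), so cor(TF, target) > cor(target, target′).
  Only star-shaped regulons of ~5 genes are recoverable *in principle*
  under the mutual-rank > 0.98 rule with a ~200-gene DE set, which keeps
  roughly each gene's top 4–9 partners — hence small regulons are a
  requirement of the retention rule, not a convenience. The four module
  templates are shaped so no pair is strongly anticorrelated, because an
  unsigned network cannot distinguish anticorrelated trajectories.
- **Background.** Non-planted genes load on a rank-6 space of latent
  smooth stage factors, with signal fraction r ~ 0.95·Beta(1.2, 2.5) and a
  random direction per gene. This reproduces two features of real
  transcriptomes that the pipeline depends on: pervasive moderate
  correlation, and a heavy-tailed connectivity distribution whose
  scale-free R² rises to a plateau near 0.9 at β ≈ 4–6 (an iid-noise
  background makes the scale-free fit degenerate and the selection rule
  meaningless). Background signal fractions stay below regulon
  correlations so background genes do not outrank planted partners.
- **Promoters.** Each gene gets a 1 kb uniform-composition promoter; genes
  alternate strands along synthetic contigs (20 genes per contig) so
  strand-aware extraction is exercised. For each planted TF→target pair
  (per-mate probability `motif_plant_rate` = 0.75) the TF's PWM consensus
  is embedded at a recorded offset and strand; planted sites therefore
  rescan at exactly the maximum attainable score. PWMs are sharp
  JASPAR-style count matrices (85/5/5/5 per column, lengths 9–13) with a
  unique consensus.

**What the generator does not emulate:** read-level artifacts (FASTQ,
alignment, multi-mapping), batch effects, GC or mappability bias,
overdispersion heterogeneity across genes, unbalanced replicate numbers,
non-consensus (sampled) motif instances, overlapping regulons, and
repressive TF→target relationships (all planted pairs are positively
correlated). Passing tests therefore demonstrate that the pipeline's
stages are implemented correctly and can recover structure of the planted
kind at realistic noise levels — not that the thresholds are optimal for
any particular real dataset.

## Problem sizes used in validation

The validation suite and the reproduction script run the full analysis on
2,000-gene studies (60 samples), 10–20 simulation seeds per stochastic
claim, 20-gene matrices for the topological-overlap oracle, 8-gene
matrices for the mutual-rank oracle, and 100 random p-vectors (length ≤
1,000) for the Benjamini–Hochberg oracle; cohort benchmarks use 200 genes
× 15 stages from four orthogonalised templates at noise sd 0.25. These
sizes make every claim cheap to recompute while keeping each estimate well
away from its acceptance margin.

## Numerical conventions and degenerate inputs

- Rounding half-up for counts; all TSV floats written with `%.10g`.
- Symmetry is enforced/checked at 1e-10; TOM symmetrised and clipped.
- Ties: mean ranks in mutual rank; smaller power on soft-threshold ties;
  lexicographic gene order in MAD and cohort-label ties.
- Zero-variance genes: error (by name) in the correlation network, p = 1
  in DE when means agree, exclusion with a warning in cohort profiling and
  MAD scaling.
- All-zero samples make TPM undefined and raise.
- Single top-level seed; stage-specific generators derive from
  `SeedSequence(seed, spawn_key)` so stages are independently reproducible.
- Reruns of the pipeline with identical config are byte-identical;
  manifests record parameters and SHA-256 digests of every output and
  contain no timestamps.

## Known limitations

- Welch-on-log-TPM is anticonservative for very low counts compared to
  count models with dispersion shrinkage; with the joint 5-fold filter
  this does not affect the reported operating points, but p-values for
  marginal genes should not be over-read.
- BH is per-contrast; family-wide control across all stage pairs is not
  applied (flagged above).
- The elbow rule inherits the elbow heuristic's geometry-dependence.
- The mutual-rank retention rule caps recoverable regulon size at ~8
  targets per TF for a ~200-gene DE set (percentile arithmetic); larger
  true regulons will be truncated to the strongest partners.
- PWM hits are treated as binary support; no positional weighting,
  conservation filtering or p-value calibration against genomic background
  models is attempted.
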