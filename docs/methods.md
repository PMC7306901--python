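# Methods

This note records the model, the defaults and the judgement calls in
`hiertype`, in enough detail to re-derive the implementation.

## Data model and preprocessing

Counts are genes × cells everywhere. Normalization divides each cell
by its library-size factor (cell total / mean total, factors mean 1;
all-zero cells get factor 1 with a warning) and applies log2(x + 1).
Base 2 and pseudocount 1 are the field's defaults and make the
"expressed" threshold of 1 on the log scale interpretable (roughly ≥ 2
normalized counts). Deconvolution-based size factors are a deliberate
non-goal; library-size factors are what the rest of the pipeline
assumes.

## Cell-type tree

Per-type mean log-expression profiles are computed over the union of
one-vs-all DE genes (top-50 filter below; if fewer than two genes
survive, all genes are used). The tree is built by recursive divisive
partitioning:

* distance = 1 − Pearson correlation between profiles;
* at each node with m > 2 types, PAM (k-medoids) is run for
  k = 2..min(kmax, m), kmax default 5. PAM uses deterministic seeding
  (global medoid, then farthest-point) and greedy swap descent, so the
  tree is a pure function of the profile matrix;
* the partition minimizing the **median split silhouette** is kept:
  each cluster of size ≥ 3 is re-split in two by PAM and scored by the
  median silhouette of its members under that sub-split; clusters of
  size ≤ 2 score 0 (treated as homogeneous). With few types most
  candidate k tie at 0, so ties are broken by the largest average
  silhouette width of the partition itself, then by the smallest k;
* children are ordered lexicographically by their smallest member
  label, making the construction invariant to row permutations.

This is a HOPACH-style approximation: the collapsing/ordering steps of
full HOPACH are omitted (irrelevant at ≤ ~40 types), and the
sub-split inside the split-silhouette is fixed at 2. Because the input
is per-type means, the tree is stable under resampling cells of
well-separated types.

## Discriminative genes

Five one-vs-rest statistics per node and child (children act as
super-labels, the union of their descendant leaves); selection is
re-done at every node:

* **DE** — two-sample t on log expression with an empirical-Bayes
  variance squeeze toward a lowess trend of log pooled variance vs mean
  (prior df 4, df = n₁+n₂−2+4 for the p-value). A moderated-t
  (limma-trend style) analogue; full limma replication is out of scope.
* **DV** — Bartlett's test (closed form, vectorized); zero variance in
  a group gives p = 1.
* **DD** — two-sample Kolmogorov–Smirnov, asymptotic p-values.
* **DP** — chi-squared (no continuity correction) on the 2×2
  group-by-expressed table, expressed = log expression > 1 (config).
* **BD** — bimodality index BI = |m₁−m₂|/s·√(p(1−p)) with pooled
  common SD s and in-group proportion p; no p-value exists, so the
  adjusted-P filter is bypassed and genes rank by BI directly.

Filter: Benjamini–Hochberg adjusted P < 0.01 (per contrast), and
|proportion difference| > 0.05. The proportion-difference cut is taken
on the magnitude: variance- and shape-type marker genes move the
expressed proportion *down* as often as up, and a signed cut would
exclude exactly the signal classes DV/DD exist for. DE additionally
requires fold change > `fc_cut` (default 1, i.e. any up-regulation).
Ranking is by adjusted P (BD: descending BI), ties by larger |effect|
then gene id, truncated at 50 per contrast; a node's per-selection set
is the union over its children. Selections that come back with fewer
than two genes fall back to the DE set, and the DE set itself falls
back to the top-variance genes (each with a warning).

**Null calibration.** Under an exchangeable null these tests are
correctly calibrated *for data satisfying their assumptions*; the
acceptance check runs them on a Gaussian null with 500 cells per side
(large enough for the KS/chi-squared asymptotics) and requires the
p-value ECDF within KS distance 0.05 of uniform. On zero-inflated
count data the same check fails for DV/DD/DP — Bartlett is not robust
to non-normality, and ties at zero make KS and chi-squared p-values
conservative and discrete. That is a property of the tests themselves,
shared with any pipeline applying them to counts; the practical
selection behaviour is still controlled (≤ 1% of genes pass the full
filter on the count-model null, which is also checked).

## Weighted kNN and the six similarities

All metrics are expressed as similarities with distance d = 1 − s:
Pearson; Spearman (Pearson on ranks); Kendall tau-b, computed exactly
as the cosine of pairwise-difference sign vectors (float32, ~1e-7
accuracy; verified against scipy and an O(n²) pair count); cosine;
Jaccard on supports binarized at log expression > 0 (config); weighted
rank correlation = Pearson on Savage scores. Savage scores use
rank 1 = largest value, score(r) = Σ_{i=r..n} 1/i (scores sum to n);
tie groups get the mean score of their covered positions.

kNN is exact and exhaustive (node-level references are small after the
tree splits the label set); ties at the K-th distance break by
reference order via a stable sort. Neighbour weights follow
w_k = (d_K − d_k)/(d_K − d_1), all 1 when d_K = d_1; votes are summed
per label, the winner needs a strict maximum (an exact tie yields no
winner and the classifier abstains).

## Node ensembles

One base classifier per (selection, metric) pair — 30 with everything
enabled. Training error ε_t is estimated by leave-one-out
self-classification (the cell's own column is excluded from its
neighbour search) over a stratified subsample of at most
`eps_max_cells` = 200 node cells; plain resubstitution would drive
every ε_t to ~0 and flatten the weighting, and 200 cells bound the
O(n²) similarity work per node. ε_t is clipped to [0.01, 0.99] so
α_t = ln((1−ε_t)/ε_t) stays finite. Children with fewer than
`min_cells_per_type` = 10 cells are unreachable (warned); a node with
fewer than two reachable children is left unmodelled and traversal
stops there. The ensemble label is argmax over children ∪ {unassigned}
of Σ α_t over agreeing classifiers (labels without votes score 0;
among exact score ties, sorted children win before "unassigned").

## Rejection: the similarity threshold

A base classifier abstains when (a) its winner's weight share is below
`weight_threshold` = 0.7, or (b) its nearest-neighbour similarity is
below the correlation threshold. With `corr_threshold = "dynamic"`
(default) the threshold is fitted per query batch by a two-component
1-D Gaussian mixture (own EM: deterministic quantile + Lloyd
initialization, tol 1e-6, ≤ 500 iterations, non-decreasing
log-likelihood), with the threshold at the posterior-0.5 crossing
between the component means.

Two granularity/robustness choices matter here:

* the mixture is fitted **per base classifier and per winning child**.
  Metrics live on different scales (a Kendall tau of 0.5 can be a
  perfect match where a Pearson 0.5 is poor), and different reference
  types have different intrinsic within-type similarity levels — a
  pooled fit detects *type* structure and can reject a whole
  legitimate cell type. Only bimodality within the pool of cells
  voting for one child is evidence of a foreign population.
* a threshold is used only with positive evidence of bimodality: the
  2-component fit must beat a single Gaussian on BIC, the means must
  differ by ≥ 0.1, and the mixture density at the threshold must be a
  genuine valley (below half the density at either component mean).
  Otherwise the fallback applies — default 0, i.e. no correlation
  rejection (the weight threshold still applies). A forced
  2-component fit on a unimodal batch splits it down the middle
  (even a pure Gaussian yields components with Ashman D ≈ 2.7) and
  would reject half of every confident batch. A fixed numeric
  `corr_threshold` disables all of this and applies one constant, for
  sensitivity analyses.

The dynamic threshold is batch-dependent by construction: a foreign
population can only be detected if the batch contains one.

## Multiscale traversal, joint classification, post hoc clustering

Cells descend from the root; the first abstention ends the path
(outcome "unassigned" at the root, else "intermediate" with the last
node's label set; leaves give leaf labels). Genes absent from the
query are dropped from each node's gene sets at prediction time,
subject to a 50% overlap floor (cross-platform queries rarely share
the full universe).

Joint classification over references r: each reference's traversal
contributes its final label with score = the ensemble's positive-alpha
weight share at the last accepted node, averaged with normalized
weights max(ln((1−ε_r)/ε_r), 0), where ε_r is the cell-weighted mean
of per-node ensemble LOO errors. The largest weighted score wins;
a cell is unassigned only when every reference abstains. Label
harmonization across references is the caller's responsibility (an
explicit mapping), matching how cross-dataset vocabularies are curated
in practice.

Unassigned cells go to a deliberately simple pluggable clusterer:
k-means on the top-500-variance genes with k chosen by silhouette scan
2..10 (fewer than 10 cells: one cluster, warned), followed by
one-vs-rest DE marker tables per cluster for manual annotation.

## Learning curves and down-sampling

The printed inverse power law a_n = b·n^(−c) + α needs b < 0 for
accuracy to *increase* toward the plateau α; this package uses the
equivalent a_n = α − b·n^(−c) with b > 0 throughout. Fitting is
bounded trust-region least squares, multi-start over c ∈
{0.1, 0.25, 0.5, 1, 2}; noiseless data are recovered to machine
precision, near-flat data are flagged degenerate. The two-component
variant fixes the transition point d, fits (b₁,c₁,b₂,c₂,α) with no
continuity constraint (the indicator form taken literally), scans d
over the interior observed sample sizes (each side needs ≥ 2 points),
keeps the smallest residual sum of squares, warns when the winner sits
on the grid boundary, and seeds each fit from the single-curve
solution so the two-component RSS can never exceed it. Inversion
n = (b/(α−target))^(1/c) uses the component active at the answer and
refuses targets at or above α.

`accuracy_grid` draws stratified training sets (≥ 2 cells per type,
at least one test cell per type) T times per size (T = 20 default) and
scores the trained classifier on the held-out remainder with the
accuracy rule that counts correct intermediates as correct.

Down-sampling thins each count x by z ~ BetaBinomial(x, ρ, p_k) drawn
as Binomial(x, q), q ~ Beta(p_k(1−ρ)/ρ, (1−p_k)(1−ρ)/ρ), with
logit ρ = τ₀ + τ₁·log(x + 0.1); E[z] = p_k·x and z ≤ x always;
p_k = 1 returns the counts unchanged. τ₀, τ₁ are user inputs
(estimating them from data is a capture-model fit outside this
package's scope).

## Seven-category evaluation

The decision table is total: (true type in reference?) × (leaf /
intermediate / unassigned prediction) → exactly one of seven
categories; intermediate correctness means the predicted node's label
set contains the true type (the reference tree's node sets, since
predictions are reference-tree nodes). Accuracy rules: `plain` scores
leaf calls only; `with_unassigned` adds the three unassigned-related
categories (correct rejections count as correct); `with_both`
additionally counts correct intermediates as correct.

## The synthetic-data generator

The generator is the package's study population, not a mock. Counts
are negative-binomial (variance μ + μ²/θ, θ = 5 by default) with
log-normal library sizes (sd 0.3) and log2-normal baseline means
(location 1.5, scale 0.8, floored at −2).

Structure comes from three layers, all scaled by `separation`
(0 gives an exchangeable null):

* **lineage programs**: every top-level class (child of the root)
  draws a genome-wide log2 shift (sd 0.6) plus strong ±2.5 on/off
  flips on 12% of genes, inherited by all its subtypes. This is what
  makes the hierarchy recoverable from mean profiles over any broad
  gene set, and what makes foreign types separable on *all* six
  metrics — without on/off structure, cosine and Jaccard cannot
  distinguish a foreign type at all. Subtypes deeper in the tree share
  their class's program and differ only through markers;
* **planted markers**: per branch-node child, one block per category —
  DE (+2 log2), DV (mean-preserving log-normal inflation, σ = 1.2),
  DD (mean-preserving ±0.75 two-point mixture), DP (+1.5 log2 on a
  −1.5 baseline, moving the expressed proportion), BD (a 50/50
  within-child on/off mixture, +4 log2, from a −1 baseline). Marker
  baselines are pinned (DE 1.5, DV/DD 3.0) because variance- and
  shape-type effects are invisible on the log scale for mostly-zero
  genes, and real marker genes are expressed genes;
* **depth attenuation**: marker effects below the top level shrink by
  0.35 per level — subtype distinctions within a class are subtler
  than class distinctions. This is also what makes intermediate
  outcomes observable: with fully separated sibling leaves, any
  transitional cell's own sampling noise tips all base classifiers the
  same way and it gets a (defensible) leaf call.

`with_single_category` produces fixtures planting exactly one marker
category with lineage programs off, for measuring one statistic's
recall of its own signal class in isolation; with everything planted
at once the categories genuinely cross-detect (an on/off bimodal gene
*is* a strong variance and distribution signal), which is a fact about
the statistics, not a defect.

Straddling populations (`simulate_mixture_cells`) average the two
parent types' mean *counts*, i.e. co-express both private programs at
half strength with the shared signature at full strength.

What the generator does not emulate: batch effects, doublets,
ambient RNA, sequencing-depth gradients confounded with type, and
realistic gene-gene correlation within a type beyond the shared
programs. Passing tests therefore demonstrate the machinery's
correctness and its behaviour under the stated population model, not
performance on any particular real platform.

## Problem sizes

Defaults used by the tests and the acceptance script: classification
fixtures of 4–6 types × 150–200 cells × 2000 genes with 25 markers per
category; recall fixtures of 3 types × 400 cells; learning-curve
fixtures of 3 types × 500 cells × 1500 genes at separation 0.45 with
sizes 15–200 and T = 5 replicates, fitted with a single
DE+Pearson base classifier. These sizes give stable statistics while
keeping a full run in minutes on one CPU; all of them are parameters,
not limits.

## Known limitations

* The dynamic rejection threshold needs ≥ `min_mixture_n` = 20 cells
  voting for a child in the query batch; predicting single cells falls
  back to weight-threshold-only rejection.
* ε_t from leave-one-out self-classification is optimistic relative to
  a held-out estimate on small nodes.
* The intermediate-call rate for genuinely transitional populations
  plateaus well below 100%: base-classifier errors are correlated
  through the query cell's own sampling noise, so a cell whose
  realized profile tilts toward one sibling is consistently called
  that sibling.
* Bartlett-based DV selection inherits Bartlett's sensitivity to
  non-normality on count data (see null calibration above).
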