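# Methods

This note documents the models implemented in `crestflow`, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a user should know about.

## Quality control and preprocessing

A cell is kept iff its non-ERCC transcript total lies in
`[min_transcripts, max_transcripts]` (defaults 5×10⁴ – 6×10⁶), its detected
non-ERCC gene count lies in `[min_genes, max_genes]` (defaults 1,000 –
10,000), and its ERCC read fraction is at most `max_ercc_fraction` (default
0.15). These defaults describe deep plate-based (SmartSeq2-style) libraries;
all five bounds are configurable, and the QC report records which criterion
each removed cell failed.

Normalization scales each cell to `target_sum` (default 10⁶) non-ERCC
transcripts and applies `log10(1 + x)`; ERCC rows are excluded from the
library size but scaled by the same factor, and zero-total cells are dropped
with a warning. Overdispersed genes are ranked by the residual of
log₁₀ variance over a degree-2 polynomial trend in log₁₀ mean, computed on
the log layer with ERCC and zero-variance genes excluded. This is a trend
residual in the pagoda2 spirit: the contract is the *ranking*, not any
particular dispersion score.

Imputation is a linear kNN smoother: the row-normalized cell kNN adjacency
with a self-loop, applied `steps` times (default 3 on a 15-NN graph).
`steps=0` is the identity; the operator is linear and leaves constant genes
untouched. It stands where a diffusion-based imputer would sit in a larger
pipeline, chosen for transparency: its fixed points and bandwidth are
obvious from the graph.

## Principal tree (SimplePPT) and pseudotime

The tree is fitted by alternating three steps until the maximum node
displacement drops below `tol` (default 10⁻⁴, `max_iter` 300):

1. responsibilities `R_ij ∝ exp(−‖x_i − c_j‖²/σ)`, row-normalized (computed
   with a per-row max shift so the kernel never underflows to all-zero);
2. edges = minimum spanning tree over current node–node euclidean distances;
3. node positions solve `(diag(Rᵀ1) + λL) C = RᵀX`, the normal equations of
   the elastic objective `Σ_ij R_ij‖x_i − c_j‖² + λ Σ_(j,k)∈E ‖c_j − c_k‖²`
   (`L` is the unweighted tree Laplacian).

Nodes are initialized by seeded k-means++ sampling. The recorded objective is
the soft-assignment free energy
`−σ Σ_i log Σ_j exp(−d_ij²/σ) + λ·elastic`, which each of the three steps can
only decrease; the tests assert this monotonicity on every run. Desk-scale
defaults are `σ = 0.1 × median pairwise squared distance` and `λ = 1`;
atlas-scale analyses on diffusion embeddings typically need a far smaller
bandwidth and stronger elasticity (e.g. σ = 5×10⁻⁴, λ = 200 at thousands of
nodes) — those are passed explicitly.

Node pseudotime is geodesic distance from a user-chosen root (edge length =
embedding distance). Cell pseudotime is either the R-weighted mean of node
pseudotimes (`soft`, the default) or the best node's value (`hard`); both
are provided because the projection through R admits either reading, and
they coincide as R concentrates. Ties in the best node break toward the
lower node id, as do all other ties in the package. Root choice encodes
external knowledge (developmental stage, stemness score); `select_root`
picks the tip maximizing the R-weighted mean of a user-supplied per-cell
score. Milestones are tips (degree 1) and forks (degree ≥ 3); a cell is
assigned to the milestone on its own root-to-tip path minimizing
|t_cell − t_milestone|, earlier milestone on ties. Probabilistic mappings
draw, per cell, one node from its row of R; they propagate assignment
uncertainty into any downstream statistic.

## Association testing and trends

The tree-dependent model is an unpenalized natural cubic spline basis of
pseudotime (df = 5 by default, knots at quantiles), fitted independently per
tree segment with its own intercept; the null is the global intercept. The
F-statistic uses the fitted design's actual rank. P-values are
Benjamini–Hochberg corrected across features (the field-default correction),
and a feature is *significant* iff `q < fdr_threshold` (default 10⁻⁴) and
its fitted amplitude `A = max − min` of fitted values exceeds `a_cut`
(default 0.025; 0.02 for regulon activities). The amplitude filter is what
keeps statistically detectable but biologically flat features out of
downstream sets. Segments with fewer than df + 2 cells are dropped with a
warning; constant features get p = 1 and a degenerate flag. Unpenalized
splines were chosen over penalized GAMs deliberately: at df 5 the fit is
stiff enough not to need smoothing-parameter selection, and the F-test is
exact under Gaussian noise (the type-I calibration test checks the 5 % raw-p
rate against its 99 % binomial interval).

`fit_trends` evaluates the same per-segment fits on equal-spaced grids
(default 50 points per segment); evaluation outside the observed range
clamps to the boundary value.

## Bifurcation analysis

Branch-specific genes are detected with the model
`g ~ s(t) + s(t):Branch + Branch` over the two-branch path, where the branch
factor is coded as a signed contrast (+1 / −1 post-fork, 0 pre-fork) — a
coding under which swapping branch labels provably leaves every p-value
unchanged. The interaction p-value is the F-test of the full model against
`g ~ s(t) + Branch`; BH across genes; candidates have `q < fdr_cut`
(default 0.1).

Each candidate is then tested for upregulation along each
progenitor→terminal path with the linear model `g ~ t` (two-sided t-test on
the slope, BH across candidates per branch) and assigned to the branch where
the slope is positive, FDR < 0.05, and the spline-fitted mean post-fork
expression exceeds the other branch's by `effect_cutoff` (default 0.2 on the
log₁₀ scale; always user-overridable, since sensible cutoffs are
bifurcation-specific). A gene qualifying on both branches with equal effect
stays unassigned and is logged.

Activation timing splits the progenitor→terminal trend into `n_bins`
equal-width pseudotime bins (default 10) and computes the relative rate
`r(b) = (f(b+1) − f(b−1)) / (max f − min f)` at interior bins, `f(b)` being
the mean fitted expression in bin b. The first bin with `r > rate_threshold`
(default 0.1 per bin step, echoed into every report) is the activation bin;
its centre is the activation pseudotime; genes activating at or before the
fork are *early*, after it *late*; a flat trend is degenerate
(not-activated), avoiding the 0/0. Note the central difference looks one bin
ahead, so the call lands near the *onset* of the rise (where the trend first
leaves baseline), about one bin before a logistic midpoint — the generator
therefore exposes `module_activation_onset`, the scale-aware 10 %-of-range
crossing of the noiseless mean curve, as the matching ground truth.

## Module-correlation dynamics

Cells ordered by pseudotime are grouped into sliding windows (size/step) or
non-intersecting blocks (trailing block kept if ≥ half-sized). Within each
window the Pearson correlation matrix over the two modules' genes gives:
intra-module correlation (mean over distinct unordered pairs within a
module), inter-module correlation (mean over all cross pairs), and per-gene
series (mean correlation with the other module's members). Genes constant
within a window are excluded from that window's pairs — never zero-imputed,
which would deflate the means — and a window with no valid pair is NaN.
Defaults: window = max(30, n/20) cells, step = window/3; both are echoed
into outputs because published window choices are rarely recoverable.
`correlations_over_mappings` repeats the computation across probabilistic
mappings and reports per-window mean ± sd (sd 0 when R is concentrated).

On the default synthetic fork this reproduces the three-phase fate-choice
signature: the two early modules' inter-correlation is positive while they
co-activate before the fork and strongly negative after it, as the branches
commit and the opposing module is repressed.

## Regulon dynamics and metaregulons

Regulon activities are consumed as AUC-style scores in [0, 1] (their
inference — GRN construction, motif pruning, cell scoring — is upstream and
out of scope). Weighting by the regulon's TF: per cell,
`w = clamp(log10 expression, 0, 1)`, weighted score = `w × score`; a TF with
log₁₀ expression above 1 leaves the score unchanged and an undetected TF
silences it. Multiplication is the implemented combination rule (documented
prominently since "weighted by" admits readings); weighting never increases
a score and is idempotent at full weight. Regulons with no TF measurement
pass through unweighted, logged.

Fitted trends are z-scored per regulon ("scaled" activity — the z-score
makes cosine distance ignore offset and positive scale, so rescaled trends
co-cluster) and clustered by Leiden on a cosine-distance kNN graph
(default 40 neighbours, reduced with a warning when regulons are fewer;
resolution 1.0; seeded). Edge weights use the smooth-kNN calibration of
UMAP-style neighbour graphs: per node, `exp(−(d − ρ)/σ)` with ρ the nearest
distance and σ set by binary search so the weights sum to log₂(k). This
local calibration matters: with flat similarity weights a dense kNN graph
pushes modularity toward merging genuinely distinct trend clusters. Cluster
labels are renumbered by the activation order (centre of mass) of their
mean trend for stable reporting, and each metaregulon trend is the exact
unweighted mean of its members' input trends. Bin summaries reduce any
feature × cell matrix to equal-width pseudotime bins (globally, e.g. 20
bins, or per tree segment, e.g. 5 bins per segment), empty bins NaN.

## Annotation and the hub state

Cell-type scores are means of per-gene min–max-scaled imputed expression
over each type's markers (z-score scaling available as an alternative).
A cell is labelled with the unique type whose score clears its threshold;
zero passing types → unassigned (no-type), two or more → unassigned
(multi-type, the discard rule). Note the multi-type rule makes the total
unassigned count non-monotone in the thresholds (a multi-type cell can
become single-type as thresholds rise); the no-type pool alone is monotone.

The hub call is community-level: Leiden communities of the cell kNN graph
whose unassigned fraction is **≥** the cutoff (inclusive convention,
default 0.8, configurable) are flagged, and hub cells are their members.
Hub markers come from a two-sided Wilcoxon rank-sum test of hub versus all
other cells on normalized expression, BH-corrected, ranked hub-elevated
first. Defaults for the community step on desk-scale data are 10 neighbours
and resolution 4.0: the fraction rule is a per-community average, so finer
communities track the hub boundary more faithfully; coarse communities
straddle it and dilute both sensitivity and precision.

## Reference mapping

Queries are correlated against all reference cells over the shared feature
set (optionally minus an exclusion list, e.g. cell-cycle-correlated genes
supplied by the caller; at least 50 shared features required). The top k
(default 5) reference cells become neighbours with weights = correlations
shifted positive (minimum neighbour correlation subtracted, ε added) and
normalized to sum 1 — a deliberately transparent scheme recorded in the
graph object. Projected coordinates / transferred values are weighted
averages (hence inside the neighbours' convex hull); the transferred label
maximizes summed weight, exact ties resolving lexicographically with a flag.

## The synthetic generator

The generator emulates the statistical structure this analysis assumes, with
full ground truth for recovery scoring:

- **Geometry**: a rooted tree of straight segments (default: an NC trunk of
  pseudotime length 1 forking into glial and sympathoadrenal arms of length
  1, allocation 0.4/0.3/0.3); cells uniform along arc length; embedding =
  backbone + isotropic Gaussian noise (default sd 0.05).
- **Expression programs** per gene module: logistic activation
  `baseline + amplitude · logistic((t − activation)/steepness)` on the
  target path; early modules additionally decay back to baseline on the
  opposing branch past the repression time (reverse logistic) — the
  co-activation-then-repression motif; late modules activate only post-fork;
  terminal type markers switch on late (or, for progenitor-identity markers,
  switch *off* near the fork); hub markers are Gaussian bumps at the fork;
  background genes are flat with heterogeneous depths.
- **Counts**: negative binomial with variance `m + m²/θ` (default θ = 5, a
  moderate overdispersion for deep plate libraries) around
  mean × lognormal library factor (default sdlog 0.2, per-cell totals
  ≈ 1.5×10⁵); ERCC rows drawn so each cell's spike-in fraction lies in a
  stated range (default 0.02–0.08); optional injected low-quality cells
  cycle through the three QC failure modes (low totals, few genes, high
  ERCC fraction).
- **Regulon activities**: five well-separated smooth templates (late rise,
  early fall, early/mid/late peaks) on normalized pseudotime, round-robin
  cluster assignment, Gaussian noise (default 0.05), clipped to [0, 1];
  TF log₁₀ expression proportional to the template (factor 2, so the AUC
  weight saturates above half activity).
- **Hub truth**: the pseudotime band in which every type-marker program is
  below 25 % of its amplitude — the operational meaning of "expressing no
  terminal-type marker signature".

Default module parameters (amplitude 100 on baseline 20; early activation at
fork − 0.4 with repression at fork + 0.15; late activation at fork + 0.6;
marker steepness 0.05) were fixed once so that the planted effects are
unambiguous at the stated tolerances — in particular the late activation
sits two bins past the fork because the rate formula's central difference
anticipates onsets by about one bin, making effects closer to the fork
intrinsically ambiguous for early/late labelling. What the generator does
**not** emulate: batch and plate effects, doublets beyond QC-violating
cells, gene–gene correlation beyond shared trends, spliced/unspliced
layers, dropout beyond NB sampling, or realistic gene-name structure.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the assumed data model, not robustness to every artefact of
real data.

## Problem sizes and determinism

All shipped analyses run at desk scale: 300–600 cells, ~1,100 genes, 30 tree
nodes, 30 regulons — sizes at which the full test suite and the acceptance
script each complete in well under a minute while every recovery target is
measurable. Every stochastic step takes an explicit seed (numpy Generator,
seeded k-means++, seeded Leiden); the pipeline derives per-stage seeds from
one configured seed, and a rerun with the same configuration is bit-identical
(verified by sha256 checksums in the run manifest). Ties everywhere break
toward the lower id / earlier pseudotime; degenerate inputs (constant
features, flat trends, empty windows or bins, missing TFs, disconnected
cells) are flagged or NaN-marked rather than silently zeroed.
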