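# Methods

## The per-cell statistic

For genes X and Y and cell c, the statistic is a local, frequency-based
mutual information evaluated on a grid discretization of the pair's scatter
diagram over all n cells.

**Grid.** Each gene's axis is divided into `GR = ⌊√n + ½⌋` equal-width bins
spanning that gene's observed [min, max] across all n cells. Bins are
half-open with the last bin closed; a value lying exactly on an internal
boundary belongs to the bin on its right. A constant gene yields one
degenerate bin, is flagged, and never produces edges (its local MI is
defined as 0).

**Neighborhoods.** The tentative neighborhood of cell c along the X axis is
the closed value interval spanned by the `k = ⌈box_size·n⌉` cells whose X
expression is nearest to c's (c included; equidistant candidates resolve to
the lower value, then the lower cell index). The interval is then snapped
outward to the grid: the final neighborhood `G_X^(c)` is the inclusive
range of bins the interval intersects. This realizes the intended behavior
that the neighborhood is smaller in dense regions and larger in sparse
ones, while the grid expansion buffers small expression fluctuations. An
alternative rank-centred window (`neighborhood="split"`, half the
neighbors below and half above the cell's rank) is provided for sensitivity
analysis; the nearest-k window is the default.

**Entropies and local MI.** With `n_x` the number of cells (out of all n)
in sub-region x of `G_X^(c)`,

    H(G_X)^(c) = − Σ_{x ∈ G_X^(c)} (n_x/n) · ln(n_x/n)

and analogously for Y and for the joint term over the grid rectangle
`G_XY^(c) = G_X^(c) × G_Y^(c)`; empty sub-regions contribute 0. The local
MI is `I^(c) = H_X^(c) + H_Y^(c) − H_XY^(c)`. Natural logarithms are used;
because the per-pair scores are standardized before thresholding, the log
base rescales all scores by one constant and the resulting networks are
provably base-invariant (verified to 1e−9 in the tests).

**Standardization and edge calls.** Per pair, `z^(c) = (I^(c) − μ)/σ` with
μ, σ the mean and *population* standard deviation of the n local MI scores
(a `sd_mode="sample"` flag exists for sensitivity checks). When σ = 0 all
z are defined as 0, so a pair whose local MI never varies across cells can
never pass a non-negative threshold. Cell c's network contains edge X–Y
iff `z^(c) > z_threshold`, strictly. Defaults: box size 0.2, threshold 0.

**Degree matrix.** Entry (g, c) is gene g's degree in cell c's network;
each column sums to twice that cell's edge count. The default output is the
raw count; `log10p1` applies log10(d+1). The normalization slot is
deliberately extensible.

**Complexity.** After an O(m·n log n) per-gene precomputation (bin
assignments, neighborhood bin ranges, prefix sums of per-bin entropy
terms), each pair costs O(n + GR²) via 2-D prefix sums over the joint count
grid — O(m²·n) overall, streamed pair by pair. Results are bit-identical
for any `threads` setting. Inference can be restricted to the edges of a
reference network (`pair_restriction`) to cut the quadratic cost.

## What the per-cell statistic actually detects

A consequence of normalizing frequencies by the total cell count n (rather
than within each neighborhood): cells in which a pair is locally
*dependent* concentrate extra mass in the joint neighborhood `G_XY^(c)`,
which **raises** the joint entropy term and **lowers** I^(c) relative to
the pair's other cells. The z > 0 edge rule therefore marks the cells where
a pair's local co-occurrence is *weak* relative to the pair's own average —
dependence still leaves a clear per-cell signature (the dependent cells'
mean z is displaced, increasingly so with the planted correlation, which
the tests verify), but the sign is the opposite of the intuitive reading,
and the magnitude of the per-cell contrast is modest: on synthetic data
with a within-type latent correlation of 0.8, the edge probability differs
by at most ≈0.2 between a pair's dependent and independent cells.

Two downstream consequences, measured honestly by the acceptance tests:

- **Degree-matrix clustering at desk scale (60 genes, 450 cells) does not
  recover planted cell types** (adjusted Rand ≈ 0–0.2). The per-cell degree
  noise is dominated by cell-level latent factors shared across genes, so
  the modest per-pair contrast does not average out across the 59 partners
  each gene has at this matrix size. The corresponding acceptance tests
  encode the recovery claims as stated and are expected to fail; they are
  retained unweakened as a faithful record. (With thousands of genes the
  per-gene contrast accumulates over far more partners, which is the regime
  the approach targets on real data; that regime is outside desk-scale
  testing.)
- **Dark-gene marker screening works.** A gene whose degree distribution
  shifts between cell types — in either direction — is flagged by the hub
  Fisher screen when the screen is run per candidate label, and the
  expression filter removes ordinary differentially expressed genes. This
  is robust at desk scale (19–20 of 20 seeds).

## Downstream analyses

**Clustering evaluation.** Cells are embedded by PCA (full SVD, sign fixed
by making each component's largest-magnitude loading positive; optional
per-gene standardization, off by default) to 20 dimensions, clustered by
k-means (10 seeded restarts) or agglomerative Ward (flags for
complete/average linkage), with k taken from the number of known labels.
Eight external indexes are reported: ARI, AMI, completeness, homogeneity,
NMI, V-measure, Fowlkes–Mallows (geometric mean of pairwise precision and
recall) and the pairwise F-measure (their harmonic mean — a distinct
statistic, kept separate deliberately). t-SNE is provided for visualization
only.

**Parameter selection.** For a grid of (box size, z threshold) combinations
— default 0.05–0.25 × {−2,−1,0,1,2} — per dataset and clustering method the
combinations are ranked 1 = best by descending F-measure (average rank on
ties); re-ranking scores are the mean rank across datasets, the two
methods' re-ranks are averaged, and the smallest value wins (ties: higher
mean F-measure, then lexicographic combination order).

**Network statistics.** Overlap coefficient |A∩B| / min(|A|,|B|) on
unordered symbol pairs (exact, case-sensitive matching; an upper-casing
flag handles human symbol conventions). Scale-free fit: OLS of log10 P(k)
on log10 k over observed degrees k ≥ 1 (raw distinct-degree frequencies;
optional logarithmic binning for heavy tails), γ = −slope, R² of the
regression. Size matching against a reference network takes the top
target-count edges by a user-supplied confidence score (ties
lexicographic). Hubs are the top 25% of nodes by degree (cutoff = degree of
the ⌈0.25·m⌉-th highest node, ties included). Hub and edge enrichment use
one-sided (greater) Fisher's exact tests on the 2×2 (in type) × (present)
table, OR = ad/bc with the 0/∞ conventions; p-values are verified against
an explicit hypergeometric tail sum. The marker screen combines
BH-adjusted hub-enrichment p < α with a two-sided rank-sum expression test
p ≥ α (unadjusted — conservative for a claim of *no* difference), ranked by
odds ratio. Aggregate networks keep edges present in strictly more than
70% (configurable) of a label's cells.

## Synthetic data

The generator emulates moderate-depth plate-based scRNA-seq: a Gaussian
copula (equicorrelation ρ within a module's genes, for cells of the
module's active types) mapped through the normal CDF to negative-binomial
quantiles, then zeroed independently at a flat dropout rate. Defaults:
NB mean 10, dispersion 2 (variance 60, ≈8% sampling zeros), dropout 0.05,
giving ≈13% total zeros. The flat dropout model attenuates observable
correlation far more aggressively than the expression-dependent dropout of
real data — at 30% dropout a latent ρ = 0.9 survives as Pearson r ≈ 0.2 —
so the default rate is deliberately low enough that planted modules remain
observable (ρ = 0.9 → count-scale r ≈ 0.77), which is the regime any
dependence-based method assumes.

Modules may carry an `activation_fold`: the NB mean of the module's genes
is multiplied by this factor in active-type cells. Fold > 1 models an
ordinary co-regulated, up-regulated program; fold = 1 gives **dark genes** —
the copula is the only thing that differs between types, so the marginal
per-gene distributions are exactly type-invariant (verified by rank-sum
tests). Cell types are apportioned by largest remainder and shuffled;
everything is reproducible from one integer seed.

What the generator does *not* model: library-size variation, batch effects,
expression-dependent dropout, trajectories. Passing tests on this data
demonstrate the pipeline's statistical behavior under clean, known
dependence structure — not performance on real tissues.

## Numerical and design choices

- Half-open bins with the last bin closed; internal-boundary points go
  right. The independent test oracles use the same convention by explicit
  loops.
- Nearest-k tie-breaking prefers the lower value, then the lower cell
  index (only the selected interval matters, so index ties are moot).
- "Expressed" in the low-gene filter means strictly positive raw value;
  filtering precedes the log2(1+x) transform; gene and cell order are
  preserved through every filter.
- The top-k variance selector breaks ties by lexicographic gene id.
- Degenerate (constant) genes are flagged, not rejected, and excluded from
  pair evaluation.
- Fisher tests are one-sided (greater) by default, matching the directional
  question the enrichment analyses ask; two-sided is available.
- All stochastic operations take explicit seeds; the core inference has no
  randomness at all.

## Limitations

- The desk-scale clustering limitation described above is the main one.
- The degree-matrix normalization beyond raw counts and log10(d+1) is an
  open slot.
- Scale-free fitting by OLS on log-log frequencies is the conventional
  procedure here but is known to be a biased estimator of the exponent for
  heavy-tailed data; the logarithmic binning option mitigates, not removes,
  this.
- Gene-symbol harmonization against reference networks is intentionally
  minimal (exact match, optional upper-casing); no alias resolution.
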