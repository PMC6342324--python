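# Methods

This note documents the statistical models, the numerical choices made
where the design was genuinely open, what the synthetic-data generators do
and do not emulate, and the problem sizes the test suite runs at.

## Per-cell count models

All model tests operate on tables of per-cell allele-assigned transcript
counts (`n_bl6`, `n_jf1`, optional `n_unassigned`, `n_dual`, `total`).

**Coin-flip (binomial) null.** All heterozygous cells share the pooled
allelic ratio p̂ = Σn_bl6 / Σ(n_bl6+n_jf1); conditional on each cell's
observed total, n_bl6 ~ Binomial(total, p̂). The test redraws every cell
10,000 times by default (configurable), recomputes the NLL at p̂ per
simulated dataset, and reports the empirical percentile of the observed
NLL. Cells with zero assigned RNAs contribute nothing to the NLL; they are
retained in tables.

**All-or-none model.** The observed table is first idealized: every RNA in
a cell adopts the cell's majority allele, exact ties broken by a fair coin.
Each simulation then applies technical noise: the two directed flip counts
(BL6→JF1 and JF1→BL6) are drawn binomially at the false-detection rates
measured in homozygous controls, then repaired symmetrically so the
simulated population totals equal the observed heterozygous totals exactly
— the repair changes the total number of flips by at most one RNA, so the
binomial variability of the noise is preserved while the population-total
constraint holds. Which RNAs flip is a uniform draw without replacement,
spread over cells by a multivariate hypergeometric on per-cell counts.
Simulated populations are processed exactly like the data: cells are
re-grouped by their own majority identity before the statistic is
computed. Without that re-grouping the null is badly miscalibrated,
because in the observed table a flip that overturns a small cell's
majority is silently absorbed by the majority assignment, and the
simulations must absorb such flips the same way. The statistic is a
two-subpopulation NLL — within cells of each (re-grouped) identity the
minority-allele count is Binomial(cell total, fdr of that identity) — and
the Pearson correlation of the simulated populations is returned as a
second null. Even so, the exact-total constraint removes variance that the
generative process has (the net flip balance is pinned), so the NLL null
is slightly narrow: in calibration runs on synthetic monoallelic data the
central-95% rule rejects ~7–8% of replicates rather than 5%.

**Negative-binomial bursting.** Moments fit per allele: p = m/v,
r = m²/(v−m) with the sample variance (n−1 denominator); burst size
(1−p)/p, burst frequency r. Underdispersed samples (v ≤ m) raise an error
rather than returning a degenerate fit. Goodness of fit: simulate datasets
of the observed size from NB(r, p) and locate the observed NLL. The
burst-size scan reparameterizes at fixed sample mean (p = 1/(1+b),
r = m/b) so every scanned configuration remains comparable to the data.
The random-pairing correlation test draws both alleles independently,
optionally applies one round of per-RNA false-detection flips, and
computes Pearson correlations; observed and simulated correlations are
both computed over **all** cells, zero-count cells included, because the
simulations are unconditional and restricting the observed side to
detected cells would bias it negative (a Berkson-type selection effect).
Elsewhere (`population_stats`) the correlation excludes zero-assigned
cells, matching how measured single-cell tables are usually summarized;
the two conventions are deliberate and documented here.

**Empirical location.** Percentile = 100 · #{null ≤ obs}/n; two-sided
p-value = 2·min(P(null ≤ obs), P(null ≥ obs)) with add-one smoothing, so
p is never 0 and never exceeds 1. "Rejection" in reports means the
percentile falls outside the central 95% band; the band is configurable.

**Detection-efficiency robustness.** With per-cell pre-downsampling totals
available, the chosen model is simulated once directly on the assigned
counts and once at full totals followed by a per-cell hypergeometric
thinning back to the assigned count; the two NLL null distributions are
compared by a two-sample KS test. For the coin-flip model the two routes
are distributionally identical (binomial thinning of a binomial), which
the implementation reproduces draw-for-draw at detection rate 1 by using
twin generator streams.

## Colocalization

Matching runs in two stages. A wide nearest-neighbour search (2.5 px
window) collects (allele − guide) displacement samples; the componentwise
median is the chromatic-aberration correction. A single global median
vector is used rather than a spatially varying field: a global vector is
deterministic, and on synthetic fields it recovers an imposed shift to
< 0.02 px even with half the allele spots spurious. After correction, each
guide is matched within the chosen radius to at most one spot per allele
channel by greedy nearest-first matching (candidate pairs sorted by 2D
distance, accepted when both spots are free); the paper-level procedure
specifies nearest-neighbour search but no conflict resolution, and greedy
matching guarantees one-to-one assignments. Guide and allele spots must
also agree in z within ±1 plane (configurable); bundled fixtures are
single-plane. Assignment: BL6 / JF1 if exactly that channel matched,
"both" if both (excluded from the unique rate), "none" otherwise.

The pixel-shift control repeats the matching after translating guide
coordinates by (+2r, +2r), estimating chance colocalization; for uniform
spurious spots at density ρ per channel it agrees with the Poisson-process
rate 1 − exp(−2ρπr²). The radius scan (0.1–2.5 px, step 0.1) picks the
radius maximizing (real − shifted) among radii whose real rate is ≥ 95% of
the maximum real rate, ties toward the smaller radius; this automates what
is otherwise a visual-inspection step, and the full scan table is emitted
for inspection. Subpixel spot refinement fits a symmetric 2D Gaussian plus
offset by least squares, falling back to the intensity centroid (flagged)
on degenerate patches. Distances are in pixels throughout; the 2.5 px ↔
360 nm equivalence is metadata.

## Focus detection and classification

Pipeline: background subtraction (Gaussian blur at 10× the LoG scale by
default — the background estimator is otherwise unspecified in the
source procedure), grayscale morphological opening, negated
Laplacian-of-Gaussian (scale-normalized), thresholding at a multiple of
the robust noise SD (median absolute deviation of the LoG response —
absolute thresholds would be tied to one scan's intensity scale), border
clearing, connected components, then min/max area, min solidity and min
intensity filters. Centroids are intensity-weighted on the
background-subtracted (clipped) image.

Per focus, each SNV channel's mean intensity over the component mask,
minus a local Gaussian-blur background sampled under the same mask, is
divided by that channel's whole-image mean; negatives clip to zero and
θ = atan2(I_JF1, I_BL6) ∈ [0, π/2]. Classification is 1-D k-means (k=2,
10 restarts, fixed seed) on θ; the critical angle is the midpoint of the
two cluster centers, θ above it → JF1. θ is invariant to rescaling both
channels; the midpoint rule makes the single separating angle explicit.

## Spatial clustering

The bounding box of the foci is tiled into equal rectangles (square grids
4×4 … 16×16 by default, i.e. 16–256 rectangles; the range is
configurable). Per occupied rectangle the BL6 fraction is computed;
empty rectangles are excluded (any fill value would be arbitrary); the
metric is the sample variance (n−1) over occupied rectangles. The
permutation null shuffles identities over fixed positions (1000
permutations by default); for equal-occupancy grids its mean matches the
hypergeometric expectation R/(R−1) · f(1−f)/m · (N−m)/(N−1). The
seeded-cluster null regenerates identities on the observed positions in
contiguous clusters of a fixed seed size at the observed ratio; one
identity simulation serves every grid, since the metric only re-bins it.
Cluster construction: iteratively pick a random unassigned cell plus its
seed_size−1 nearest unassigned neighbours; cluster labels are a shuffled
quota of round(n_clusters·p) BL6 labels, residual imbalance beyond one
cluster's worth corrected by flipping one random cluster. Seed matching:
per grid, argmin over seed sizes of |observed variance − mean simulated
variance| (ties toward smaller); the estimate is the mean of per-grid best
seeds with its SD. Matching against the mean of the 500 simulated
variances (not, e.g., the median) is the point summary used throughout.

## Synthetic data: what it does and does not emulate

Generators are bit-reproducible: one root seed, named child streams per
operation (`SeedSequence([seed, crc32(name)])`), so partial re-runs
reproduce identical output. Defaults encode the tissue regime the
analyses target: per-cell totals Poisson(λ=3) (measured kidney means are
~2.6–3.5 RNAs per cell; the measured studies condition on observed totals
and state no totals distribution, so Poisson is this package's explicit
choice, flagged in the config), allelic ratio 0.5, false-detection rates
0–2%, ~50–60% of guide spots assignable (coloc_prob 0.3 + 0.3), chromatic
shift (0.4, −0.3) px with 0.15 px localization jitter, spurious spot
density 1e-4 px⁻², and uniform cell positions.

Not emulated: realistic optics (the PSF is an isotropic Gaussian; images
are single-plane), tile stitching and scan reconstruction, anatomical
substructure (cortex/medulla) or any non-uniform cell density, spatially
varying chromatic aberration, and cell-segmentation errors (cell labels
enter as given). Passing tests therefore demonstrate the statistical
machinery under the stated generative assumptions, not robustness to
those imaging artifacts.

## Problem sizes in the test suite

The acceptance-style tests run at desk scale: calibration with 200
populations of 500 cells at 1,000 simulations each; discrimination with 20
replicates of 1,000 cells at 500 simulations; spatial recovery with 20
layouts of 2,000 cells, grids 4×4–16×16 (step 2) and 120 simulations per
seed size (the seed-1/permutation equivalence uses 2,000 draws per side);
correlation nulls at 10⁴ simulations × 10³ cells; colocalization fields of
3,000–6,000 guide spots (the pixel-shift oracle averages four independent
fields to tame configuration noise); foci scenes of 50 blobs in 512²
images. These sizes are the package's own reproducibility choices; all
tolerances are stated in the tests themselves.

## Known limitations

- The all-or-none NLL null is mildly anti-conservative (see above); the
  correlation statistic is unaffected and is the stronger discriminator in
  practice.
- The moments NB fit requires overdispersion; near-Poisson data should be
  handled via the burst-size scan's small-b limit rather than the direct
  fit.
- Greedy nearest-first matching is order-independent but not globally
  optimal (not a minimum-cost assignment); at realistic spot densities the
  difference is below measurement noise.
- `estimate_seed_size` assumes the observed positions are a fair sample of
  the tissue; strong density gradients bias the grid variance for coarse
  grids.
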