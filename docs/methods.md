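# Methods

This note documents the models and procedures implemented in hexseq, the
assumptions behind them, and the design choices made where the underlying
assay description left the algorithm open.

## Array geometry

Wells live on a bounded hexagonal lattice in axial coordinates (q, r); the
file format uses odd-row offset (row, col), the natural indexing of a
row-staggered chip, and the two are converted only at the I/O boundary.
Hexagonal graph distance is the axial closed form
(|Δq| + |Δr| + |Δq + Δr|)/2, which equals BFS shortest-path distance on any
bounded sub-array that is hex-convex — true for the full rectangular chips
used here and verified exhaustively in tests. A *layer* is the set of wells
at a given distance; interior layers have 6l wells, edge layers are
truncated with no wrap-around (the chip is physical). The assay's published
description fixes neither the chip's row/column counts nor the hex
orientation; the default is 24 rows × 32 columns (768 wells, matching the
slide's aspect ratio and the column-oriented gradient design), and both
dimensions are configurable.

## Demultiplexing

Read 1 (26 cycles) is split positionally: bases 1–10 are the UMI, 11–26 the
spatial barcode. Observed spatial and PCR barcodes are corrected against
their whitelists at Hamming distance ≤ 1, with equidistant ties discarded;
the well-map loader checks that the whitelist's pairwise distance is ≥ 3,
which makes distance-1 correction unambiguous for true barcodes with one
substitution. The published processing states only "UMI deduplicated", so
UMI collapse is exact string match within (cell, gene) — no directional
graph collapse. Cell QC defaults are the assay's printed thresholds
(500–10,000 UMIs, 100–15,000 detected genes, ≤1% mitochondrial fraction,
all bounds inclusive); droplet-platform data takes different bounds through
the same parameters. Mitochondrial genes are recognized by a configurable
gene-name prefix (`mt-`/`MT-`) after stripping the species namespace, and a
gene's species comes from its id prefix (`hg38_`/`mm10_` by default),
mirroring alignment to a joint human/mouse reference.

## Species QC

A cell is called human or mouse when the majority species holds ≥ 66% of
its UMIs, reading the "less than 66% → collision" rule with an inclusive
boundary; cells with zero human+mouse UMIs are undefined and excluded. Lin's
concordance correlation coefficient uses population (1/n) moments, Lin's
original definition; the difference from sample moments is O(1/n).
Gradient concordance pairs observed per-column human fractions (collision
and undefined cells excluded) with the 21-column design — fractions
1.0, 0.9, …, 0.0 at the center and back up to 1.0, i.e. 11 distinct ratios
with human-only flanks and a mouse-only center column.

## Ambient-RNA decontamination

Generative model: every transcript of cell *c* in cluster *k* carries a
Bernoulli hidden state; with probability 1 − θ_c it is drawn from the
cluster's native categorical gene distribution φ_k, otherwise from a
contamination distribution η_k, and θ_c has a Beta(α, β) prior (default
(1, 1), i.e. flat). η_k is the native-count-weighted average of φ_j over
clusters j ≠ k, recomputed every M-step, so the contamination signature is
"everything the other populations express". Inference is plain EM with MAP
point estimates for θ (not a variational posterior): the E-step computes the
per-entry contamination responsibility z, the M-step updates θ_c from the
responsibility-weighted counts and φ_k from the native-weighted counts.
The EM objective (log-likelihood plus log prior) is asserted non-decreasing
every iteration; convergence is declared when the largest per-cell change in
θ falls below `tol` (default 1e-4, default cap 200 iterations). The fit is
deterministic — it has no internal randomness.

Two numerical choices matter:

- **Initialization.** φ_k starts from the cluster's observed profile with
  `theta_init` (default 0.3) times the pooled other-cluster profile
  subtracted and clipped at zero. This matters because the likelihood is
  *exactly invariant* under φ_k → (1−λ)φ_k + λη_k, θ_c → (θ_c − λ)/(1 − λ):
  a cluster profile can absorb any constant share of its contamination
  signature, so the data alone cannot pin the origin of θ. The subtraction
  starts the fit at the contamination-maximal end of this ridge, where
  counts that look like the other clusters are treated as contamination.
- **Identification.** After convergence each cluster is shifted back along
  the ridge so that its least-contaminated cell has θ = 0. This convention
  ("at least one cell per cluster is clean") is exactly
  likelihood-preserving, is inert whenever some cell already sits at θ = 0,
  and removes the otherwise arbitrary dependence of θ's origin on the
  starting point.

Consequences worth knowing: when clusters have disjoint gene supports, θ_c
is recovered *exactly* as the fraction of the cell's counts on the other
cluster's support (machine precision); planted Beta(2, 8) contamination
between overlapping random profiles is recovered to within ~0.01 in the
per-cluster median at 2,000 cells × 500 genes; but on perfectly clean data
whose cluster profiles overlap substantially, the estimator retains a small
positive floor (≈2% at 1,000 counts/cell in our simulations) because along
the flat ridge nothing distinguishes that residue from real contamination.
Species-separated clean data collapses to zero exactly.

Before fitting mixed-species data, mouse genes with log(total counts in
human cells + 1) > 6 are removed: the human spike-in is a contamination
control, and a mouse transcript that abundant in human cells would dominate
the contamination signature. Decontaminated counts are the per-entry
posterior native expectation, floored to integers in `X` (downstream count
models want integers) with the real-valued matrix kept in
`layers["native_expected"]`; corrected counts never exceed raw counts. The
pipeline order is fixed as outlier-gene removal → fit/decontaminate → cell
filtering.

## Proximity score

For well w, t_w counts its tumor + reference cells (default labels MC38 and
hepatocyte — the parenchymal type strictly tied to non-tumor tissue) and
p_w is the tumor fraction among them. Layer means p_{w,l} are
cell-number-weighted over the layer's wells with t > 0. The layered score is

    s_w = [u₁ p_w + Σ_{l=1..L} u_l p_{w,l}] / (u₁ + Σ_{l nonempty} u_l)

with exponential weights u_l ∝ d^{−l} normalized over L = 10 layers and
d = 1.05, so the well's own composition carries the same weight as its
layer-1 neighbours. Two deliberate deviations from a literal reading of the
source description: (1) the raw sum u₁p + Σu_l p_l has total weight
1 + u₁ > 1, so we divide by the realized total weight to keep s ∈ [0, 1],
matching the published 0-to-1 color scale; (2) p is the *tumor* fraction so
s ≈ 1 means tumor-rich, matching the published figure semantics — the
literal hepatocyte-fraction orientation is the exact mirror 1 − s and is
available via `orientation="reference"`. Wells with no tumor/reference
cells drop their own term; layers with none drop theirs; the remaining
weights renormalize (whether the original analysis renormalized at tissue
edges is unstated — without renormalization edge scores would be biased
down). Wells below `min_cells` total cells are left unscored.

The seeded linear variant for tissues with a single tumor axis assigns
score 1 to user-chosen seed wells and s = max(0, 1 − l/L) at hexagonal
distance l from the nearest seed (L = 10); seed choice is a user input, as
in the original analysis. Cells inherit their well's score.

## Gene modules

Expression is prepared by library-size normalization to 10,000,
log1p, per-gene standardization, and clipping negatives to zero — a
non-negative approximation of regularized-NB Pearson residuals (the
published pipeline used SCTransform, whose internals are out of scope; the
downstream operations depend only on the basis ranking). Factorization is
rank-20 NMF by seeded multiplicative updates on the Frobenius objective,
with an optional nonsmooth-NMF smoothing matrix S = (1−s)I + (s/q)11′
interposed (the published smoothing parameter is unstated; default s = 0).
The objective trace is non-increasing and the fit is deterministic given the
seed.

"Top contributing" genes of a module are the longest *leading* run of its
descending-coefficient ranking in which every gene loads strictly higher on
this module than on every other (ties break the run) — the most literal
reading of "top consecutive genes". Cross-tissue matching takes, for each
module in tissue A, the tissue-B module with the largest top-200 gene
overlap (ties to the smaller B index, reported), discarding pairs under 25%
overlap; the 25% boundary itself is kept. Per-module cell-type fractions:
mean expression per gene within each type, median over the module's genes,
normalized to sum to one. Spatial projection computes per well the median
over cells then mean over module genes; the high/low threshold is the
cells-per-well-weighted average of the well statistics (the published
phrase "weighted by the number of cells per well" is ambiguous between
weighting the statistic and the threshold; we weight the threshold, which
reduces to the plain average when occupancy is constant). "Above" is
strict: wells at the threshold are low, zero-expression wells are labeled
none.

## Proximity-associated differential expression

For each gene, counts across the chosen cell type are modeled as
NB2 (Var = μ + αμ²) with log link, a cubic B-spline basis of the proximity
score (internal knots at score quantiles, `n_knots` = 4 by default), and a
log total-UMI offset. The spline basis drops its first column in favour of
an explicit intercept; the association test is a Wald test that the spline
coefficients are jointly zero (null: expression flat in score). Dispersion
is per gene by the Pearson moment equation Σ(y−μ)²/(μ+αμ²) = n − p, solved
by bisection — first on the intercept-only fit, then refined once on the
alternative fit; the GLM itself is solved by IRLS. This replaces the
NB-GAM smoother of trajectory-inference packages with the same null
hypothesis. At n = 500 cells and dispersion 0.5 the observed type-I error
is 0.056–0.063 at nominal 0.05 (1,000 null genes) and power for a 2-fold
ramp exceeds 0.95. Constant genes get p = 1 (flagged); non-converged fits
are flagged and excluded from correction. P values are Benjamini–Hochberg
corrected, and genes at q < 0.05 are classified by the argmax of their
fitted curve over a 50-point score grid: top third of the score range →
intratumor, bottom third → intratissue, otherwise boundary (the published
grouping criterion is unstated; flat curves default to boundary with a
flag). Cells with null scores are dropped before fitting.

## Synthetic data

The generators are pure functions of (design, seed) and emulate the study's
conditions: a 24 × 32 chip; Poisson cells/well with mean 13 (the expected
occupancy of the assayed chip); a half-plane or layer-radius disk tumor
domain; four murine cell types (hepatocyte, MC38, MSC, myeloid) with
40-gene marker blocks boosted 2³-fold over a lognormal baseline; NB2 gene
counts at dispersion 0.5; per-cell depths lognormal around
base_mean × n_genes. The species-mixing generator realizes the 21-column
gradient, with an `exact_fractions` mode (fixed occupancy, exact per-well
ratios) for noiseless-design checks and balanced cross-species doublets
(two cells splitting one library's depth) for planted collisions. Ambient
contamination draws θ_c ~ Beta(2, 8) by default (mean 20%) and resamples a
Binomial(total, θ_c) subset of each cell's molecules from the pooled
other-population profile, preserving totals. FASTQ emission writes the
assay's library layout (R1 = UMI + spatial barcode at 26 cycles, R2 = a
98-cycle synthetic gene tag standing in for alignment, I1/I2 = library and
PCR indices), with geometric per-molecule read duplication (mean 2
reads/UMI, giving ≈50% reported saturation) and optional per-base
substitution errors on read 1.

What the simulations do *not* capture: real ambient RNA is not a clean
resampling of other clusters (debris is biased toward abundant transcripts
and lysis-prone types); sequencing errors here are substitutions on read 1
only, with no quality-score structure or indels; cell types have no
within-type continuum; and doublets beyond species co-encapsulation are
absent. Passing tests therefore certify the algorithms against their own
generative assumptions, not performance on real libraries.

## Problem sizes

Default verification runs use a 768-well chip for geometry and score
checks; 2,000 cells × 500 genes for contamination recovery; 500 cells ×
1,000 null genes (plus 200 effect genes) for test calibration; and a
~240-cell, 120-gene tissue for demultiplexing round trips — sizes chosen so
the whole suite completes in about a minute while keeping Monte-Carlo
tolerances tight.

## Known limitations

- The contamination model's ridge non-identifiability (above) means θ on
  clean, strongly overlapping clusters has a small positive floor; per-cell
  θ for lowly covered cells is noisy, and the clean-cell identification
  convention can under-call contamination in a cluster whose every cell is
  contaminated.
- The Wald association test is mildly liberal at moderate n (as Wald tests
  are); the reported calibration band was measured at n = 500.
- Hamming-1 correction assumes barcode whitelists with pairwise distance
  ≥ 3; denser whitelists degrade to discard-on-ambiguity.
- `tumor_proximity` recomputes layers per well (O(wells × L) ring walks);
  at 768 wells this takes a few seconds, which is fine for chip-scale data
  but would want caching for much larger arrays.
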