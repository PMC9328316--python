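# Methods

`reefscape` re-implements a seascape-genomics workflow for reef-building
corals: from genotyping-by-sequencing (GBS) SNP tables and environmental
rasters to spatial predictions of *genetic offset* — the distance between
a population's present-day gene–environment state and the state implied
by substituting future climate. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
test bed does and does not establish.

## Quality control

Filters run in a fixed order: contaminant flag → locus call rate →
sample call rate → repeatability → coverage → minor allele frequency →
Hardy–Weinberg → secondary-SNP collapse → clone removal. Thresholds are
strict inequalities (call rate and repeatability > 0.70, MAF > 0.05,
coverage > 10×), matching DArT-style practice. The order removes the
noisiest axes first so later frequency-based stages see stabilised data;
the chain is a fixed point on its own output.

The source criteria name Hardy–Weinberg equilibrium without a scope.
Pooled-sample HWE conflates Wahlund structure with genotyping error, so
we test per site with the Wigginton–Cutler–Abecasis exact test
(samples ≥ 10 per site), adjust per site by Benjamini–Hochberg at
`hwe_alpha = 0.05`, and remove a locus only when rejected in more than
half of its testable sites.

Secondary SNPs on a shared sequencing fragment are collapsed to one
locus per fragment (highest call rate; ties to the lowest
position-in-fragment, then lexicographic ID), since within-fragment SNPs
are effectively linked.

Clones: the clone-calling threshold is the largest pairwise distance
observed within any technical-replicate group. The distance is the
proportion of pairwise-complete loci with unequal codes (normalised
Hamming); a raw Euclidean variant is selectable, as the two conventions
are conflated in common descriptions of this procedure. Samples joined
by distance ≤ threshold form clone sets by transitive closure; the
highest-call-rate member of each set is retained.

## Connectivity statistics

*F*\_ST follows Nei's gene-diversity formulation: per locus,
H\_S = mean over populations of 2p(1−p)·2n/(2n−1) and
H\_T = 2p̄(1−p̄) from the unweighted mean frequency; the multilocus
estimate is the ratio of sums 1 − ΣH\_S/ΣH\_T (more stable for
low-diversity loci than a mean of per-locus ratios, and the convention
of the common R implementations). Significance and confidence intervals
come from bootstrapping loci (1000 resamples by default, seeded);
negative estimates are truncated to 0 for reporting and kept internally.
Expected heterozygosity is the across-locus mean of 2p̄(1−p̄); allelic
richness uses El Mousadik–Petit rarefaction at the smallest per-group
allele count.

The hierarchical AMOVA partitions squared Euclidean distances between
genotype code vectors (pairwise-complete loci) across
systems / reefs-within-systems / sites-within-reefs / within-sites,
with method-of-moments variance components using the standard
unbalanced-nested-design coefficients and Φ statistics. Permutation
p-values move units at the tested level: samples among sites, sites
among reefs, reefs among systems.

The neighbour-joining tree is built on Slatkin-linearised distances
F\_ST/(1−F\_ST) (scikit-bio's Saitou–Nei implementation; negative branch
lengths clamped to 0). DAPC mean-imputes and scales the code matrix,
retains principal components to ≥ 95% cumulative variance (bounded by
n−1 — a fixed large retained-PC count is meaningless at 26-site scale),
selects K by BIC = n·log(WSS/n) + K·log n over k-means solutions
(20 restarts), and keeps all discriminant axes.

## Outlier and gene–environment scans

The Bayesian outlier/GEA machinery this pipeline stands in for is
replaced by two testable frequentist scans whose *decision roles* are
identical (a neutral/outlier partition, and an environment-linked locus
set):

* **Permutation F\_ST outlier scan.** Per-locus Nei F\_ST against a null
  built by permuting individuals among populations (2000 permutations by
  default), one-sided p = (1+#{perm ≥ obs})/(n\_perm+1), BH-FDR at 0.05.
  Because permutation p-values are floored at 1/(n\_perm+1), BH can only
  reject when many loci are jointly extreme — conservative under the
  null, powerful under real differentiation. The raw statistic's null is
  *panmixia*, so in a genuinely structured organism nearly every locus
  exceeds it; the pipeline therefore builds its neutral panel with the
  `center=True` variant, whose statistic is the per-locus F\_ST minus
  the across-locus mean (applied to observed data and every permutation
  alike), i.e. a test for *excess* differentiation over the genome-wide
  background — the decision the Bayesian outlier machinery it replaces
  actually makes. Both variants control the FDR under the
  no-differentiation null.

* **Logistic GEA scan.** For each locus × variable, a logistic model of
  individual allele presence (both the carrier and the homozygote
  indicator are fitted; the better-supported orientation is kept) on the
  site-level variable, significant only when *both* the likelihood-ratio
  (G) and Wald tests pass the Bonferroni- (default) or BH-corrected
  threshold — the dual-test convention of individual-based GEA scans.
  Fits are batched: every locus shares the per-variable design matrix,
  so Newton iterations run vectorised across loci.

Individuals within a site share that site's allele frequency, so
classical per-individual tests are overdispersed under hierarchical
structure. Both statistics are therefore structure-aware: G is scaled by
a per-locus quasi-binomial dispersion estimated from site-aggregated
Pearson residuals and referred to F(1, n\_sites − d); the Wald statistic
uses a reef-clustered CR1 sandwich variance with an F(1, n\_reefs − 1)
reference. In calibration runs on nested null data (no environmental
effect) this controls the family-wise error at the nominal level, while
clines of slope 2 on a standardised variable remain detectable in ~90%
of replicates at 26 sites × 20 samples.

Two modes: `univariate`, and `pop_corrected` with DAPC cluster-membership
probabilities as covariates. The corrected mode is deliberately
conservative when environmental gradients align with the population
structure (the within-cluster signal is all that remains — a true
confounding, not an artefact), so the pipeline's default adaptive-locus
selection uses the univariate scan; the corrected mode quantifies how
much of the signal survives a structure adjustment.

The scan consumes *signed* (z-scored) site values. The
absolute-environmental-distance standardisation
(|e−ref|/max|e−ref|, reference = across-site median by default) is
implemented for distance-based association models, but it folds a
monotone cline at the reference and is therefore not fed to the
logistic scan.

Adaptive sets: `gdm_set` = loci with ≥ 1 significant association;
`gf_set` additionally requires polymorphism in > 20% of populations.
A locus is excluded from the "neutral" panel when flagged by either
scan.

## Gradient forest

Per SNP, a random-forest regression of site allele frequency on the raw
environmental predictors (bootstrap rows, √p candidate predictors per
split, unlimited depth; per-SNP seeds derive deterministically from the
master seed so results are independent of execution order). SNPs with
out-of-bag R² ≤ 0 are dropped. Each split's impurity reduction
accumulates into 201 equal-width bins along the split predictor's
observed range; the per-SNP bin profile is rescaled to the SNP's
permutation importance for that predictor, divided by the binned density
of observed values (floor 1e−6), renormalised, and averaged across SNPs
with R² weights. Cumulative sums give monotone step curves whose final
values are the overall importances, and which together define the
environment → biological-space transform (values below/above the
observed range clamp to 0 / the total importance).

Permutation importance is computed on out-of-bag samples per tree. When
a predictor has a companion correlated beyond |r| = 0.8, its permutation
runs within quantile strata (4 by default) of the most-correlated
companion — a one-companion approximation to conditional permutation
that discounts importance shared with a collinear variable; full
conditional-inference forests are out of scope. The reference
configuration is 2000 trees per SNP; at 26 observations, rankings are
stable from a few hundred trees, which the tests and bundled pipeline
use.

## Generalized dissimilarity model

Genetic dissimilarity between sites is the Euclidean distance between
allele-frequency vectors over the `gdm_set`, rescaled by its maximum to
[0, 1] (an F\_ST/(1−F\_ST) alternative is selectable; no single
convention is canonical here). Each predictor is expanded in three
order-2 I-splines (integrated M-splines, knots at min/median/max, built
as partial sums of the degree-2 B-spline basis). The model

d̂\_ij = 1 − exp(−(a₀ + Σ\_p Σ\_k c\_pk |I\_pk(x\_pi) − I\_pk(x\_pj)|))

is fitted by IRLS with an inner non-negative least squares step
(all coefficients and the intercept ≥ 0) under a binomial deviance
objective; convergence at coefficient change < 1e−8 or 500 iterations.
Performance is % deviance explained; predictor importance is the sum of
its I-spline coefficients; per-predictor significance comes from
permuting that predictor's site values and refitting (100 permutations
by default). A geographic-distance I-spline term is off by default and
available by flag.

## Offsets and scenario comparisons

The study area is the union of 50 km haversine buffers around sites
(very few coral larvae disperse farther); each buffered cell takes the
reef-system label of its nearest site. Future stacks replace SSTmax and
SSTrange by the mean over pseudo-AOGCM member layers; all other
variables are held at present values (anomaly-class variables are too
collinear with the replaced ones to project independently).

GF offset = ‖T(present) − T(future)‖₂ per cell through the
cumulative-importance transform; GDM offset = predicted
present-vs-future dissimilarity minus the identical-environment baseline
1 − exp(−a₀), so no change ⇒ exactly 0. PCA (centred, unscaled) of the
transformed cells renders similarity maps with PC1–3 rescaled to RGB
0–255 (deterministic sign convention; degenerate components render
mid-grey). Between-system tests use Kruskal–Wallis with
Bonferroni-corrected Dunn post hocs, or two-way ANOVA
(system × scenario) with Tukey HSD; cells are subsampled (seeded,
≤ 5000/system) because raster cells are spatially autocorrelated and
would otherwise pseudo-replicate.

## Synthetic seascape

The generator emulates the study design the pipeline targets — 26 sites
nested in 4 reef systems (2–3 reefs each, 2–3 sites per reef) across a
12° latitudinal span on a shallow shelf — with known truth serialized in
a manifest that, with the seed, fully determines the dataset:

* **Environment**: each variable = latitudinal trend + smooth Gaussian
  random field (Gaussian-kernel smoothing, length scale 8 cells) + white
  noise, on a 120×120 grid by default. SSTmax increases equatorward
  (≈ 27.5 °C poleward to ≈ 31.5 °C north, the observed range of the
  emulated coastline); tidal range and SSTrange also increase northward.
  One anomaly variable (TSA) is constructed to correlate with SSTrange
  at |r| ≈ 0.83, exercising the collinearity pruning. Bathymetry is a
  west-deepening shelf so the 0–40 m mask keeps a contiguous band;
  nodata holes are planted for the gap-filling stage.
* **Genotypes**: neutral loci follow nested Balding–Nichols sampling
  (defaults F\_system = 0.10, F\_reef = 0.02, F\_site = 0.01; ancestral
  frequency Uniform(0.05, 0.95)); selected loci (5% by default) have
  site frequency inverse-logit(a + b·z) with slope b = 2 on the
  z-scored driving variable and a ~ Uniform(−1, 1). Genotypes are
  Binomial(2, p) with 2% MCAR missingness; technical replicates redraw
  alleles at 1% error; clones are exact copies. 20 samples/site and
  1200 loci by default (the scale of a filtered GBS panel).
* **Futures**: SSTmax deltas interpolate linearly from the poleward end
  (e.g. +4.0 °C under the extreme scenario) to the northern end
  (+2.0 °C), mirroring the strong mid-latitude warming contrast of the
  emulated region; SSTrange shifts by 40% of the local delta; members
  add mean-zero noise (SD 0.15 °C).

What passing tests show — and do not. The generator produces binomial
sampling noise around smooth clines and exchangeable hierarchical
structure; it has no linkage disequilibrium beyond shared fragments, no
isolation-by-distance within systems, no selection-drift dynamics, and
its environmental fields are stationary Gaussian. Calibration and power
results therefore demonstrate correctness of the estimators and
decision rules under the designed conditions, not performance guarantees
on real reef data, where confounding between geography and environment
is stronger and less symmetric.

## Numerical and scale choices

Logistic fits: vectorised Newton–Raphson, ridge 1e−9, step clip ±5,
separation flagged at |β| > 15 (non-estimable, never significant).
IRLS/NNLS tolerances as above. Distances are haversine km
(R = 6371.0088); nearest-neighbour queries use chord distance on the
unit sphere through a KD-tree; grid resampling is nearest-centre in
degree space, exact for rectilinear grids. Rasters are exchanged as
ESRI ASCII grids (DX/DY headers for non-square cells) with a YAML layer
manifest.

Test and acceptance runs use the same code paths at reduced sizes
(40×40–60×60 grids, 200–1000 loci, 100–500 trees, permutation depths
99–1000) chosen so decision thresholds are resolvable at those sizes;
`scripts/acceptance.py` runs the full preset (120×120, 1200 loci, four
scenarios, 500 trees per SNP).

## Known limitations

* The centered outlier statistic accounts for the mean background
  differentiation but not for its between-locus drift variance, so it
  remains liberal under strong structure (roughly a quarter of loci
  flagged at the default synthetic scale); a full FDIST/FLK-style
  drift-variance null is a natural extension.
* The univariate GEA scan inherits environment–structure confounding;
  the corrected mode removes it at a substantial power cost when clines
  align with structure. Both are reported.
* Conditional permutation handles one companion predictor; clusters of
  ≥ 3 mutually collinear predictors still share importance.
* The out-of-bag R² ≤ 0 screen retains roughly 5–10% of pure-noise SNPs
  at 26-site sample sizes (a small-sample property of the OOB R²
  statistic, independent of tree count); curves averaged over many SNPs
  dilute these, but individual retained-SNP lists should be read with
  that false-keep rate in mind.
* GDM fits all site pairs as independent observations (the standard
  construction); p-values from the permutation test, not the deviance,
  should be used for inference.
* Kriging is approximated by k-nearest inverse-distance weighting for
  gap filling (deterministic, parameter-light; a pluggable interpolator
  hook accepts alternatives).
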