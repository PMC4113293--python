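# Methods notes

This note records the statistical models implemented in `streambeta`, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Diversity partitioning

Diversity is measured as Hill numbers of order q = 0 (richness) and q = 1
(effective Shannon diversity, exp H′ in nats). The partition is
multiplicative: β_w = γ/α with α the mean per-site diversity and γ the
diversity of the pooled counts. Sites are weighted equally; the intended
design is balanced (equal sites per region), and no abundance-weighted
alpha is offered.

For q = 1 the "mean per-site diversity" is ambiguous: the arithmetic mean
of per-site exp H′, or the Hill decomposition exp(mean H′). Both are
implemented (`alpha_mode="arithmetic" | "jost"`). Arithmetic is the
default because it is the plain reading of "average effective diversity";
the Jost mode is the one under which β_w ∈ [1, n_sites] holds exactly and
β_w is invariant to replicating every site's counts, and it is what the
bound-checking tests use. Every output row records the mode. The per-site
median diversity is reported alongside the mean as a descriptive summary.

## Individual-based null model

The randomisation pools all individuals of a region as species-labelled
tokens, applies one uniform permutation, and partitions the tokens
sequentially by the original per-site totals. Row sums (site abundances)
and within-region column sums (species abundances, hence γ) are preserved
by construction — this is the conditional distribution of the data given
both margins, i.e. a multivariate-hypergeometric table null.

Choices:

* the SES denominator is the sample SD (ddof = 1) of the null
  distribution;
* the p-value is one-sided (null β_w ≥ observed) with the (r+1)/(n+1)
  correction, so p ∈ (0, 1];
* `n_iter` defaults to 999 in the library; calibration tests use 99–199
  where the replicate count already controls Monte-Carlo error;
* each region consumes an independent child of one `SeedSequence`, so
  results do not depend on the number or order of other regions;
* a null distribution with zero SD (e.g. a single-species region) flags
  the result degenerate and reports the SES as missing (NaN), never as 0.

The shuffle is applied independently within regions; there is no
among-region randomisation (regional species pools are taken as given).

## Occupancy–frequency modality

Occupancy classes are (0, w], (w, 2w], …, (1−w, 1] with w = 0.05 by
default (20 classes); a proportion exactly on an edge belongs to the lower
class, and class membership is computed in integer arithmetic (occupancy
is a ratio of site counts), so edge cases are exact. Zero-occupancy taxa
are excluded.

The modality test places each of the S observed taxa in one of c classes
with probability 1/c under the uniform null. p-values are exact tails:
binomial for each extreme class, and a joint trinomial exceedance over
(leftmost, rightmost) counts for bimodality. The number of classes pooled
per tail is a parameter (`n_extreme`, default 1). Classification at
α = 0.05: both tails significant and the joint tail significant →
bimodal; otherwise whichever single tail is significant; otherwise not
significant. Note the naming caveat in the module docstring: "left/right"
refer to the histogram's extreme classes (left = lowest occupancy), while
parts of the core–satellite literature call a mostly-rare community
"right-skewed"; users should check which extreme class carries the excess.

A known property of the exact tails: the test is conservative because the
binomial is discrete. At S = 100, c = 20 the achievable size closest to a
nominal α = 0.05 from below is 0.028 (rejecting at k ≥ 10); the nominal
level itself is not attainable. This is inherent to exact tail tests, not
a defect of the implementation; a mid-p variant would trade exactness for
size closer to nominal and was deliberately not adopted.

## Dispersion and habitat heterogeneity

Sørensen dissimilarity is computed on presence/absence
(d = 1 − 2a/(2a+b+c)); a quantitative Bray–Curtis variant is available
behind the same interface. Habitat distances are Euclidean on z-scored
variables; standardisation uses the sample SD across **all** sites, not
within groups, so genuine between-group differences in spread are
preserved — this is exactly what the heterogeneity comparison measures.

PCoA Gower-centres −½D² and keeps negative-eigenvalue axes explicitly as
imaginary coordinates (eigenvalues within 1e−10 of zero, relative to the
largest magnitude, are dropped). Squared distances to the group centroid
(coordinate mean, not spatial median) are real-part minus imaginary-part;
negative squared distances — possible for semi-metric input — are floored
at zero before the square root, with a logged count of floored values.

The homogeneity-of-dispersion test is a one-way ANOVA F on the centroid
distances z (df = g−1, N−g). Significance comes from permuting the
least-squares residuals z_j − mean(z in own group) across all sites with
group sizes fixed, recomputing F on the permuted residuals, and applying
the (r+1)/(n_perm+1) convention; permuting raw z values is available as a
sensitivity mode. `n_perm` defaults to 999. Sums of squares below a
relative tolerance of 1e−12 are treated as zero so that configurations
with exactly equal dispersions return F = 0 rather than 0/0 noise.

The implementation was cross-checked against the standard R reference for
this procedure (vegan's `betadisper` with centroid type) on a small
fixture; the per-site distances agree to 1e−7 and F to 1e−6.

Habitat heterogeneity is the same machinery applied to the six in-stream
variables (depth m, velocity m/s, channel slope, canopy % cover, substrate
index mm, macrophyte % cover); Euclidean input has no imaginary axes, so
the scores equal raw-space distances to the standardized-coordinate
centroid.

## Inference

All-subsets OLS over up to 10 predictors, including the intercept-only
model. Log-likelihoods and R² come from ordinary Gaussian OLS
(statsmodels); AICc, Akaike weights and summed predictor weights are
computed here. k counts the intercept, the slopes and the residual
variance (the Burnham–Anderson convention, matching MuMIn), so a
univariate model has k = 3. AICc is undefined when n ≤ k+1; single fits
then report it as missing, and the all-subsets search either raises or,
when the analysis unit is aggregated region means (`unit="region"`),
skips infeasible subsets on request. Models within ΔAICc < 2 of the best
are flagged as the top set; no coefficient model-averaging is performed.

The default analysis unit for the dispersion–environment regressions is
the site (n = number of sites); region-mean aggregation is a mode. Partial
Spearman correlation uses the first-order formula on rank correlations
(cross-checked against pingouin).

## Synthetic generator

What it emulates: a balanced R-region survey (default 8 × 15 sites) with

* regional pools as overlapping contiguous windows (~50 % overlap) of a
  global species list, sized by `gamma_per_region` (default declining
  linearly 60 → 32 to mimic a broad-scale richness gradient);
* lognormal pool SADs (`sad_sigma`, default 1.0 — a typical
  moderately uneven community);
* per-site totals NegBin(mean 200, dispersion 5), the order of a
  several-minute kick-net count, with overdispersion between sites;
* Gaussian environmental filtering on one latent axis: sampling weights ∝
  SAD × exp(−(e_j − µ_s)²/2τ²). τ = ∞ (the default) recovers neutral
  multinomial sampling exactly — the same conditional structure the null
  model preserves, which is what makes the calibration tests meaningful;
* habitat variables derived from the latent axis plus noise, so a wider
  `gradient_range` raises both realized habitat heterogeneity and
  compositional dispersion, and chl-a, Pfankuch and steepness with
  region-level structure;
* a regression generator with known linear coefficients and
  region-structured predictors.

What it does not emulate: spatial autocorrelation and dispersal kernels,
temporal dynamics, detection error, taxonomic aggregation, and any
covariance among habitat variables beyond their shared latent axis.
Passing calibration tests therefore demonstrates correctness of the
statistics under the stated sampling model, not robustness to those
real-data complications.

All randomness flows from a single seed through per-region
`SeedSequence.spawn` substreams; adding a region never changes earlier
regions' draws.

## Problem sizes in the validation suite

The statistical validation runs at the design scale of 8 regions × 15
sites. Replicate counts were fixed at values whose Monte-Carlo standard
errors are small relative to the asserted bands: 200 replicate datasets
(199 shuffles each) for neutral calibration, 100 for the filtering signal
plus 30 per point of a 4-point τ grid (99 shuffles), 500 two-group
datasets (199 permutations) for the dispersion test's type-I error, and
10 000 draws for the modality-test size.

## Known limitations

* The exact modality test is conservative at practically relevant S and c
  (see above).
* β_w for q = 1 with the default arithmetic alpha can exceed the
  [1, n_sites] Hill bounds slightly; use `alpha_mode="jost"` when the
  bounds matter.
* The all-subsets search is exponential in the number of predictors and
  deliberately capped at 10.
* The permutation F-test assumes exchangeable residuals; strong
  imbalance with heteroscedastic groups is outside its remit.
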