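# Methods

This note records the models, the synthetic data-generating process, the
numerical choices, and the design decisions taken where the workflow left
them open.

## Temporal Fourier decomposition

Each per-pixel monthly series (a whole number of years, no gaps) is reduced
to 14 components. Harmonics at 1, 2 and 3 cycles per year are estimated by
least squares on cosine/sine regressors; for regular whole-year sampling
this coincides with the discrete Fourier transform, and least squares was
chosen so the estimator extends naturally to missing months later. The
series is mean-centred before projection — identical in exact arithmetic,
but it keeps a constant series at exactly zero amplitude in floating point.

Choices that needed fixing:

* **Phase unit** — month of the cycle's peak in [0, 12), counted from the
  first month of the series, rather than radians. P1 ≈ 6.5 reads directly
  as "annual peak in mid-July" for a January-start series. Conversion:
  φ = 2πk·P/12. Anyone comparing against software that reports radians or
  normalized phase must convert first.
* **Variance convention** — VR is the population variance (denominator N)
  of the raw series; each harmonic contributes A_k²/2 (Parseval), so
  D_k = (A_k²/2)/VR and DA = D1+D2+D3 ≤ 1 up to noise. A zero-variance
  series defines all D_k and DA as 0.
* **MN/MX** come from the raw series, not the fitted curve: they are data
  summaries, not model summaries.
* Phases are treated as linear quantities downstream (clustering,
  regression). With annual peaks confined to summer months this is safe;
  it would not be for species with peaks near the December/January wrap.

## Synthetic landscape and survey

The generator produces the statistical structure the analysis assumes,
not realistic geography:

* **Land cover** — Gaussian-smoothed white noise thresholded at the
  cumulative class-proportion quantiles. This yields spatially
  autocorrelated patches with class counts matching the configured
  proportions up to ties. Default proportions: 15% urban, 30% sampled
  agricultural, 20% excluded (arable) agricultural, 30% natural, 5% water.
* **Seasonal covariates** — per class, an annual + bi-annual harmonic with
  white monthly noise; class means, amplitudes and the annual peak month
  are perturbed by independent smooth spatial fields (correlation length
  ≈ grid/16 cells, i.e. a few km at 1-km cells) so every component varies
  within classes and remains identifiable. Magnitudes are loosely
  temperate-European (LST in °C with ~8–10 °C annual amplitude, NDVI/EVI
  in index units, population density in persons/km², zero over water).
  Excluded arable land carries the strongest vegetation-index seasonality
  (crop green-up/harvest) — the signature by which its unsuitability can
  be learned from pseudo-absences.
* **Truth model** — suitability = logistic(intercept + Σ β_j z_j) over
  named derived features z-scored across valid cells. Standardizing makes
  the intercept a prevalence dial (logistic(intercept) ≈ mean suitability)
  and the β comparable across features. An option clamps suitability to 0
  on excluded cells for ablation studies.
* **Survey** — trap counts per stratum by largest-remainder rounding of
  n·proportion (ties in the fixed stratum order urban, agricultural,
  natural), e.g. 766 traps at 0.4/0.4/0.2 → 307/306/153. Traps fall
  uniformly at random without replacement within their stratum (each
  location visited once); presence is Bernoulli(true suitability at the
  cell) and positive traps get a 1+Poisson(2) count. The sampling week
  (1–30, an April–October season) is recorded but deliberately influences
  nothing after presence/absence reclassification — which is exactly why
  counts are reclassified. The catch-count distribution is cosmetic; only
  presence/absence is consumed downstream.

What the generator does **not** emulate: real geography and climate
reanalysis, observation error in the rasters, imperfect trap detection,
multi-species interactions, and spatially autocorrelated residual presence
(presence draws are independent given the suitability surface). Passing
tests therefore demonstrate correctness of the machinery and recoverability
under the stated conditions, not field performance.

## Occurrence preparation

Counts ≥ 1 become presence. One record per 1-km cell; a presence in the
cell beats any absences (presences are more informative than absences),
ties within a class keep the lowest point id (order-independent).
Pseudo-absence count is configurable; the default is 5% of observed
records, since the emulated survey fixed 43 points for its particular
excluded area but stated no general rule. Placement is uniform at random
over free excluded cells — whether the original points were placed
uniformly or by expert choice is unknown, so the simplest reproducible
rule is used. Cells are half-open with 0-based row/col indices and
floor((coord − origin)/cell_size) assignment.

## Model families

All three share: balanced training samples (equal presences and absences),
an ensemble whose prediction is the plain arithmetic mean of submodel
outputs in [0, 1], and child seeds derived as SeedSequence(master, index)
so runs are reproducible and order-independent. Default bootstrap size per
class m = min(class counts) capped at 150.

**NLDA.** k-means (10 restarts, Euclidean on z-scored features) runs
separately within presences and absences; each cluster becomes a Gaussian
discriminant class with prior ∝ cluster size and covariance regularized by
λI, λ = 10⁻⁶·trace/dim (escalated ×10 on Cholesky failure). Suitability is
the posterior probability of the presence super-class, computed with
log-density stabilization. Open choices taken: k = 4 clusters per class
(captures multimodal niches at desk-scale samples; configurable); both
clustering and the discriminant densities use the 41 generic variables by
default (DEM + means, amplitudes, extrema, variance and phases of MIR,
dLST, nLST and NDVI — "LST" expanded to both day and night products), since
estimating 74-dimensional covariances from ~100-point bootstraps is
hopeless; a full-feature option exists. Per-bootstrap variable importance
is not defined by the original procedure; here each submodel ranks
variables by the Fisher separation ratio (squared class-mean difference
over pooled within-class variance) on its own balanced sample, and ranks
are averaged across submodels.

**Forest.** Five balanced subsets (minority class whole, majority class
downsampled without replacement); one classification forest per subset
(500 trees, mtry = ⌊√p⌋, Gini splits, grown to purity, per-tree bagging —
scikit-learn's RandomForestClassifier); the ensemble averages the five
forests' presence probabilities and is *not* additionally bootstrapped —
the in-forest bagging already serves that role. Leaves output presence
fractions (a hard-vote mode exists). Importance is the forest's mean
decrease in Gini impurity, averaged over subsets. Tree count and mtry are
conventional classification-forest defaults, exposed in the config.

**GLM.** Logistic regression fitted by IRLS on z-scored features
(tolerance 10⁻⁸ on the log-likelihood, ≤ 100 iterations). Quasi-complete
separation — routine when p ≈ n on balanced bootstraps — triggers a flagged
ridge refit (λ = 10⁻⁴ on coefficients, intercept free); standard errors
come from the (penalized) Fisher information, and fits with a numerically
singular information matrix are excluded from ranking. An optional
pre-filter drops the later member of any feature pair with |r| > 0.95
(keep-first over the canonical feature order) and zero-variance features.
Within each converged fit variables are ranked by |z| descending; ranks are
averaged across fits. Residual spatial autocorrelation is checked with a
Moran's I correlogram of the deviance residuals of the ensemble-mean
prediction, using binary distance-band weights over 10 equal-width bins up
to half the maximum pairwise distance (beyond that, few pairs remain and
the statistic is erratic); empty bins and zero-variance residuals yield
NaN rather than errors. The permutation-null expectation of each bin's I
is −1/(n−1).

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) at a suitability
threshold of 0.5 (no threshold was prescribed; it is reported in the
output and configurable). Confidence intervals are percentile intervals
over 2000 stratified bootstrap replicates — presences and absences
resampled separately with replacement at their original sizes — at the
95% level; the percentile method is the simplest one consistent with
stratified resampling and is recorded in the report. Evaluation reuses the
training table by design: the models are descriptive suitability scores,
and the interface deliberately offers no hidden split, so reported
accuracies are optimistic in the usual way.

## Experiments and problem sizes

The canned experiments (`mosquitosdm.experiments`) fix the study
conditions: a 50×50 km landscape, a 766-location stratified survey (the
emulated survey's size), 38 pseudo-absences (5% of records), and three
planted drivers — the annual peak months of NDVI, MIR and dLST with
standardized logit effects 2.0, −1.8 and 1.6. Phase components were chosen
as drivers because they have no structural correlates among the other
components (MX ≈ A0 + A1 makes mean/extreme drivers ill-defined as
"exactly three features"), so driver recovery is unambiguous. The ablation
experiment uses a 40×40 landscape, 400 traps, a zero-suitability excluded
class and 43 pseudo-absences, and contrasts the forest's mean predicted
suitability over excluded cells between paired runs that differ only in
pseudo-absence count. The acceptance script runs 10 recovery studies and
5 ablation pairs; the test suite runs 20 and 10.

## Known limitations

* Phases are linear, not circular, throughout (see above).
* NLDA importance is a package-defined proxy (Fisher ranks); other
  implementations of the method may rank differently.
* The GLM screen's keep-first rule privileges the canonical feature order;
  with heavily collinear stacks the *named* survivor of a correlated pair
  is arbitrary even though the fitted ensemble is essentially unchanged.
* ESRI ASCII grids are the only raster format; they carry no CRS, so
  coordinates are interpreted as projected km.
* Serialized ensembles (joblib) are a convenience for resuming runs, not a
  stable interchange format across package versions.
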