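# Methods

This note documents the models, numerical choices and defaults behind
`speceff`, and what the synthetic-data generator does and does not emulate.

## The data-generating picture

A cohort is a set of plant-extract batches from two classes — wild-type
(YJH-like) and cultivated (JH-like) chrysanthemum — each measured as an
HPLC-DAD chromatogram and as a panel of bioactivity endpoints.  A subset of
the *common* peaks (peaks present in every batch) is causal: their
abundances drive all activity endpoints.  The marker-identification task is
to recover that subset from the peak-area matrix X (samples × common peaks)
and the activity matrix Y (samples × endpoints).

### Synthetic cohorts

`synthetic.simulate_cohort` generates, per batch:

- **Peak areas**: log-normal within class.  A peak's mean area and
  coefficient of variation (default CV 0.4) are class-specific.  Common
  peaks (default 16) appear in both classes, with the cultivated class
  1.3× more abundant by default; class-specific extra peaks appear only in
  their class — many low-abundance ones for the wild type (default 10,
  mean area 20 mAU·min) and few high-abundance ones for the cultivated
  type (default 2, mean 80), mirroring the richer but dimmer profile of
  wild material.  The distributional form is an assumption; no source data
  constrain it.
- **A latent activity factor**: the causal peaks (default 3, drawn among
  the common peaks) share a per-sample standard-normal factor entering
  their log-areas with loading 0.8 (mean-preserving).  Bioactive compounds
  of one biosynthetic family co-vary across batches; without this
  correlation each causal peak's marginal correlation with the response is
  algebraically capped at w_i/‖w‖ ≤ 0.58 for three causal peaks, which no
  per-peak importance measure could separate from chance correlation at
  n = 16.  The factor is what makes the cohort's signal-to-noise "generous";
  set `causal_latent_sd=0` for fully independent areas.
- **Chromatograms**: sums of symmetric Gaussians (height = area/(σ√2π),
  default σ = 0.12 min) on a 0–75 min grid, plus optional linear drift and
  iid noise (default sd 0.3 mAU).  Retention times get a per-sample
  Gaussian shift (sd 0.05 min) so that peak matching is non-trivially
  exercised.  Exponential tailing and detector saturation are not modeled.
- **Bioactivities** (`simulate_bioactivity`): every endpoint is an affine
  function of the same causal signal — the weighted sum (weights
  U(0.8, 1.5)) of the standardized causal areas — plus iid Gaussian noise
  (default sd 0.1).  With zero noise each endpoint is exactly affine in
  the causal areas.  Endpoints are therefore strongly mutually correlated,
  as real antioxidant panels are.

`simulate_metabolome` plants exactly `n_differential` features whose
second-group mean is `fold_change`× the first-group mean, injects zeros
completely at random, and assigns identification scores uniform on [0, 60].

What passing tests on these cohorts do **not** show: robustness to
retention-time drift beyond a global shift, co-eluting peaks, non-Gaussian
peak shapes, batch effects in the assays, or structured (intensity-
dependent) missingness in the metabolome.

## Fingerprint stage

Peaks are local maxima above height and prominence thresholds
(scipy's peak finder); bounds are the flanking minima of the prominence
base and areas are trapezoidal integrals between them.  Matching is greedy
agglomeration ordered by peak height: each peak joins the nearest cluster
(running-mean retention time) within `rt_tolerance` (default 0.25 min) that
does not already contain a peak from the same sample.  The reference trace
is the pointwise median across samples ("simulative median chromatogram");
the similarity index is the cosine of the angle between intensity vectors
(Pearson mode behind a flag), computed after linear resampling onto the
union grid clipped to the common time range.  No similarity acceptance
threshold is enforced; the index is reported.  Missing areas stay NaN —
never zero — so "common peak" (no missing entry in any sample) is exact.

## Bioassay stage

Scavenging/inhibition/CAA formulas are exact closed forms; values outside
[0, 100] % are reported as computed, with a warning, since clamping would
hide assay problems.  The CAA unit integrates the 5-min fluorescence grid
by the trapezoid rule.  EC₅₀ fitting parameterizes the 4PL on log-EC₅₀
(positivity for free), initializes from the linear-interpolation crossing
of the half-maximal response, and uses tight tolerances (1e-14) so
noiseless round-trips recover parameters to ~1e-8; an interpolation-only
mode is available.  Hill-sign and floor/ceiling swaps are canonicalized
after the fit.  The Y-matrix builder requires every endpoint for every
sample and harmonises lower-is-better endpoints (EC₅₀-type) by reciprocal
(default) or negation so that larger always means more active.

## Multivariate core

Scaling is unit-variance (N−1 denominators) for fingerprint–efficacy
regression — the common default of commercial chemometrics software —
and Pareto for metabolomics intensities.  The first element of every
weight/loading vector is forced non-negative for reproducibility.

**PLSR** is NIPALS with deflation of both blocks.  For a single response
each component is closed-form (w ∝ Eᵀu in one pass); for multivariate Y
the inner loop iterates to a relative score tolerance of 1e-9 (budget
2000 iterations; exceeding it raises a flagged convergence error).  With
as many components as the rank of X the coefficients B = W(PᵀW)⁻¹Cᵀ
coincide with ordinary least squares, which the tests verify to 1e-8.
Per-component R²X and R²Y come from the deflation identities
(tᵀt)(pᵀp)/SSX and (tᵀt)(cᵀc)/SSY.

**Q²** is 1 − PRESS/SS under k-fold cross-validation (default sevenfold),
with scaling re-estimated inside each training fold and fold assignment a
seeded permutation dealt round-robin.  The pipeline picks the smallest
component count attaining the maximal Q², capped at three components — the
natural budget of a 16-sample cohort and the depth at which the latent
structure of these data is exhausted.

**VIP** uses the weight-based formula with SSY_a weights; mean(VIP²) = 1
holds to machine precision and is asserted.

**OPLS-DA** codes classes −1/+1 (centered), strips `n_orthogonal`
components with zero covariance to the class vector, then takes one
predictive component; the S-plot pairs each variable's covariance and
correlation with the predictive score.  Q² is computed by k-fold CV on the
orthogonal-filtered matrix.  The **permutation test** (default 200 label
permutations) reports add-one p-values for both R²Y and Q², with floor
1/(n+1); under label exchangeability the p-value is uniform, which the
calibration test checks at the 5 % level.

**Volcano**: Welch t-test per feature, fold change as second-group over
first-group mean, Benjamini–Hochberg adjustment, and a selection flag
VIP > 1 AND raw p < 0.05.  Raw p is used for the flag because the
univariate test validates the OPLS-DA VIP screen rather than acting as an
independent discovery scan; the adjusted p is emitted alongside.
Hierarchical clustering delegates to scipy (Ward/Euclidean default; scipy's
deterministic lowest-index tie-breaking).

## BP-ANN and contributions

One hidden layer, tanh units, linear output; inputs/outputs standardized
against the training split and back-transformed for reporting (MSEs are in
original response units).  Training is Levenberg–Marquardt on the analytic
Jacobian: damping μ starts at 1e-3, ×10 until a step lowers the training
MSE (so the accepted-step MSE sequence is non-increasing by construction),
÷10 after acceptance; training stops when μ exceeds 1e10, the MSE change
falls below tolerance, or the validation MSE has not improved for
`patience` accepted steps, restoring the best-validation weights.  The
split is a seeded random 70/15/15 partition.  As μ→0 the update is the
Gauss–Newton step — one-step exact for residuals linear in the weights —
and as μ→∞ it tends to the scaled gradient; both limits are tested.

Garson's algorithm partitions |input→hidden| weights within each hidden
unit, weights the shares by |hidden→output|, and normalizes to 100 %.
Olden's signed connection-weight products are available behind a flag.
Because single-net Garson rankings are noisy when a 16-sample cohort is
split three ways, the pipeline averages contribution ratios over a
9-member ensemble (different seeds for initialization and split) and uses
a 4-unit hidden layer at this cohort size; the generic default
ceil((n_in+n_out)/2) remains available and both are config-exposed.

## Marker consensus

A common peak is a marker when (i) its VIP exceeds 1.0 in the full-data
model *and* in every leave-one-out refit, and (ii) it ranks within the
top-k ensemble contribution ratios, k defaulting to the number of peaks
passing (i).  The leave-one-out requirement is stability selection with no
tuned constant: a marginal VIP of ~1.1 produced by chance correlation at
n = 16 almost always dips below 1 when some single sample is removed,
whereas genuinely causal peaks (VIP ≈ 2) never do.  Ties in contribution
rank break by peak id, so the selection is deterministic.

## Metabolomics filter chain

Fixed order: missingness filter → half-minimum imputation → score filter;
each filter emits a log with conserved counts.  The per-group missingness
rule reads "zeros exceeding 50 % within each group" with a strict boundary
(exactly 50 % is retained) and, by default, removal only when the fraction
exceeds the cut in *every* group, so a feature well measured in one group
survives; the stricter any-group reading is a flag, since the quantifier
is genuinely ambiguous.  Scores of exactly 36 are retained (≥ 36 rule).
The identification score is consumed as input; vendor scoring is out of
scope.

## Problem sizes

The shipped defaults are the package's study scale: cohorts of 16 samples
with 16 common peaks and 3 causal markers; 25–50 replicate cohorts for
recovery rates; 100 replicates for EC₅₀ recovery (8 two-fold dilutions in
triplicate, 2 % response noise) and for permutation-test calibration
(200 permutations each); metabolomes of 200 features, 10 samples per
group.  All generators draw from one seeded `numpy` Generator per call and
never touch global random state, so every number in the test suite and in
`scripts/acceptance.py` is reproducible from the seed alone.

## Known limitations

- Peak matching is greedy; pathological retention-time drift patterns can
  split or merge clusters that a global alignment would handle.
- OPLS-DA supports exactly two classes; multi-class designs are out of
  scope, as are kernel/sparse PLS variants.
- The BP-ANN is deliberately small; deep architectures, regularization
  schemes and ensembles beyond seed-averaging are out of scope.
- The similarity index has no acceptance threshold; interpretation is left
  to the analyst.
- KEGG pathway enrichment and vendor compound-identification scoring are
  consumed upstream/downstream of this package, not computed.
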