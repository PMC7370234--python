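# Methods

This note documents the models and procedures `trailstrat` implements, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Synergy scoring and response classes

Combination effects are judged against Bliss independence on the
fraction-affected scale: `f_exp = f_A + f_B − f_A·f_B` (the fractional
product — surviving fractions multiply under independent action).  The
per-condition synergy score is the *difference* `S = f_obs − f_exp`, not a
ratio: the difference is bounded in [−1, 1], symmetric around additivity,
and averages meaningfully over a factorial design.  A sample is called a
synergistic responder when its mean score over all combination conditions
exceeds `synergy_threshold` (default **0.1**, i.e. ten percentage points of
excess killing).  The threshold is a classification convention, not an
estimated quantity; it is configurable and logged.  An optional
`normalize-to-control` mode first corrects all fractions for spontaneous
death, `(f − f_ctrl)/(1 − f_ctrl)`, clipping to [0, 1] with a warning
(replicate noise can produce small negatives); the default is off because
dead-cell fractions are typically reported directly.

Grid validity requires a monotherapy partner for every combination
condition; this is enforced structurally at construction, so scoring can
never silently pair a combination with a missing reference.

## Standardization

Each protein is mean-centred and divided by its sample standard deviation
(n−1 denominator).  The panel mixes immunoblot fluorescence (arbitrary
units) and receptor counts (molecules/cell); per-protein standardization is
what makes these commensurable, and no additional cross-assay rescaling is
applied — each protein's scale is absorbed into its own (μ, σ).
Zero-variance proteins are rejected by name rather than imputed or dropped
silently.  New samples are always standardized with the *training*
parameters.

## PCA with Kaiser retention

PCA is performed on the standardized matrix, equivalent to
eigendecomposing the protein correlation matrix; it is computed as an SVD of
`Z/√(n−1)` for numerical stability, and cross-checked in the test suite
against a brute-force `eigh` of the explicitly formed correlation matrix
(agreement to 1e−8).  Components with eigenvalue > `kaiser_threshold`
(default **1.0**: a component must explain more than one protein's worth of
variance) are retained, capped at `n_pcs_max` (default **6**, the
dimensionality the classification operates in).  If nothing clears the
threshold — possible on tiny sub-panels late in the reduction — one
component is retained with a warning.  Sign indeterminacy is removed by
fixing each loading column's largest-magnitude entry positive, which makes
models byte-reproducible and serializable.

With n = 16 samples and p = 19 proteins the correlation matrix has rank
≤ 15; trailing eigenvalues are exactly zero and the eigenvalue sum still
equals p (trace identity), which the suite asserts.

## LDA segmentation

The retained-PC space is segmented by a two-class linear discriminant with
pooled within-class covariance: `w = Σ⁻¹(μ₊ − μ₋)`,
`b = −½(μ₊ + μ₋)ᵀw + log(π₊/π₋)`, posterior `σ(wᵀx + b)`.  Priors default
to **empirical** class frequencies (a 12:4 panel legitimately informs the
boundary); equal priors are available and are what the null-calibration
tests use.  A singular pooled covariance — easy to produce with 15-sample
folds in six dimensions — is detected by its smallest eigenvalue and
ridge-regularized (`ε·I`, `ε = 1e−6·trace/dim`) with a warning rather than
failing.  On an exact posterior tie the configured `tie_policy` decides;
the default **low** refuses to call a responder on a knife edge.  The
implementation is cross-checked against scikit-learn's
`LinearDiscriminantAnalysis` posteriors in the test suite.

## Leave-one-out cross-validation

Every fold refits standardization, PCA and LDA on the remaining n−1 samples
and projects the held-out profile with the fold's parameters only.  Folds
whose training labels collapse to one class are reported unevaluable and
excluded from denominators, which keeps behaviour deterministic on
pathological inputs.  Sensitivity and specificity take *synergistic* as the
positive class.

A property worth knowing when interpreting null experiments: LOOCV of an
LDA-type classifier on uninformative features is **not** centred at the
majority rate or even exactly at 0.5.  Holding a sample out shrinks its own
class and inflates that class mean's variance, which biases held-out
predictions toward the larger training class; with a 12:4 design this pushes
null accuracy well above 0.5 under either prior convention.  The package's
chance-calibration checks therefore use a balanced (8/8) permuted-label
design with equal priors, for which 0.5 is the correct chance reference;
measured null accuracy then sits inside the 95% binomial band.

## Merit ranking and panel reduction

Merit is the absolute Pearson correlation between a protein's values and the
class indicator (synergistic = 1), averaged over the training portions of
`cv_folds` (default **10**) stratified folds.  Fold assignment shuffles
within class with `rng_seed` (default **20170101**) and distributes
round-robin, which tolerates classes smaller than the fold count (a 4-sample
class simply misses some folds; every training portion keeps both classes).
Absolute rather than signed correlation is used because pro- and
anti-apoptotic proteins associate with responsiveness in opposite directions
and both directions are informative.  Exact merit ties break by canonical
panel order, then lexicographically.  A no-CV mode (plain full-data |r|)
exists for comparison.

Reduction drops the lowest-ranked protein per iteration (ranking fixed from
the full panel), re-runs LOOCV with `n_pcs_max = min(6, p_current)`, and
descends to `reduction_min_proteins` (default 2).  Because the stopping rule
behind a fixed published subset size is not derivable from the outcome
alone, the selected subset is defined explicitly: the smallest set whose
LOOCV accuracy is within `reduction_tolerance` (default **0**) of the
full-panel accuracy.

## mRNA→protein interpolation and the in silico trial

Cohort values arrive as log2(FPKM-UQ+1) and are back-transformed to the
linear scale (`2^v − 1`) before curve creation; interpolating on the linear
scale is the primary mode, with a log-scale alternative deliberately *not*
the default since the point-to-point construction is defined on expression
values.  Per protein (per mapped gene — ranges are per-gene, not pooled),
the standard curve is the line through (cohort mRNA min, panel protein min)
and (cohort mRNA max, panel protein max); two points make the point-to-point
curve exactly linear, endpoints map exactly, and the map is monotone.
Estimates are clamped to the panel range — impossible when the same cohort
defines the curve, but possible when a frozen map is deployed on new
patients — because the PC space is only trained on that range; clamped-cell
counts are logged.  The shipped gene↔protein table covers the 11-protein
reduced predictor (XIAP, CASP3→Procaspase 3, CYCS→Cytochrome C, MCL1,
BIRC2→cIAP1, BAX, BID, BCL2L1→Bcl-xL, DIABLO→Smac, FADD, BAK1→Bak); a
full-panel map is left to the user because cFLIP and the TRAIL receptors
have isoform/paralog ambiguities no default should hide.  Trial prevalence
is simply the predicted-synergistic fraction of the cohort.

The min–max construction assumes the cohort's expression extremes correspond
to the panel's — a strong assumption that is exactly what the "proof of
concept" framing of such trials acknowledges; the package makes it explicit
rather than calibrating slopes it has no data for.

## Synthetic data: what it emulates, and what it does not

`gen_panel` draws log-scale profiles from a low-rank Gaussian factor model
(rank **4**, half the unit within-class variance shared) with a class-mean
shift of `effect_size` within-class standard deviations on the informative
proteins, alternating sign to mimic opposed pro-/anti-apoptotic
associations; columns are exponentiated (log-normal marginals — protein
quantities are positive and right-skewed) and scaled by per-protein
baselines spanning ~`scale_heterogeneity` decades (default **1.0**) so that
standardization is exercised on realistic magnitude spreads.  Defaults — 12
synergistic + 4 low samples, 19 proteins, 11 informative, effect size
**2.0** — mirror the small-n, heterogeneous regime the pipeline targets;
2 sd is a realistic "clearly present but imperfect" biomarker effect that
leaves LOOCV accuracy in the high-80s/low-90s rather than saturating.

`gen_grid` emits the 15-condition factorial design (3+3 monotherapies, 9
combinations) with a constant super-independence boost plus independent
replicate noise on every condition; independent noise on the monotherapies
keeps the recovered mean score an unbiased estimate of the boost.

`gen_cohort` draws patient protein profiles from the class-conditional
log-normal fit to a panel (clipped to the panel range so the min–max map is
invertible), inverts the per-protein standard curve, and re-applies
log2(x+1) with optional additive measurement noise (`noise_sd`, log2 units).
Two anchor patients carrying the exact panel min/max profiles are appended
by default so that re-fitting the interpolation from the generated cohort
reproduces the generating map bit-for-bit.  True labels are returned for
recovery testing but never consumed by the pipeline.

None of the generators attempt mechanistic apoptosis signalling, dose
dependence of killing beyond the injected boost, batch effects, censored or
missing measurements, or mRNA–protein decoupling (the cohort generator is
monotone by construction).  Passing tests therefore demonstrate the
*statistical machinery* — not that any particular real cohort satisfies the
monotonicity or range assumptions.

## Numerical conventions and problem sizes

Standardization asserts column means < 1e−10 and sds within 1e−10 of 1; PCA
oracle agreement is to 1e−8; interpolation round-trips to 1e−8.  All
randomness flows through `numpy.random.default_rng` seeds carried in
configs or function arguments, and every stage is bit-reproducible given
identical inputs.  The test suite and the acceptance script run their Monte
Carlo checks at sizes chosen to make the statistics decisive while keeping a
full run in seconds-to-minutes on one CPU: 200 random panels for the PCA
oracle, 200 permuted-label LOOCV replicates for null calibration, 100-seed
boost recovery, 500-seed merit null, and 365–500-patient synthetic cohorts.

## Known limitations

* With n = 16, LOOCV estimates have wide binomial uncertainty; single-sample
  differences (e.g. 13/16 vs 14/16) are not meaningful distinctions.
* Empirical priors encode the training class balance; deploying the
  predictor on populations with different prevalence shifts the effective
  boundary.
* Mid-ranking merit order is sensitive to fold partitions at this sample
  size; only the extremes of the ranking are stable across seeds.
* The interpolation maps transcript to protein through two points per gene;
  it cannot represent saturation, translational regulation or protein
  stability differences.
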