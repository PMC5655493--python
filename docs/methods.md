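# Methods

## The problem

During pregnancy a woman's body weight follows a smooth individual
trajectory, but cohort studies can rarely afford more than a handful of
measurements per participant: typically a self-reported prepregnancy weight
(W0, placed at gestational week 0), up to three clinic measurements in
trimester windows A (8–13 w), B (14–27 w) and C (28–36 w), and a
self-reported highest weight (WH, placed at the gestational age at birth,
≥ 37 w).  This package reconstructs each woman's continuous weight curve on
[0, 42] weeks from those 3–5 irregular, noisy records, quantifies the
uncertainty of the reconstruction, compares it with a parametric
mixed-effects benchmark, and regresses the implied gestational weight
change on prepregnancy BMI, diet and physical activity.

## Sparse functional principal component analysis

The model is a Karhunen–Loève expansion observed with error:

    Y_ij = X_i(T_ij) + ε_ij,
    X_i(t) = μ(t) + Σ_k ξ_ik φ_k(t),

with smooth mean μ, orthonormal eigenfunctions φ_k of the covariance
operator G(s,t) = cov(X(s), X(t)), uncorrelated scores ξ_ik with
var(ξ_ik) = λ_k, and i.i.d. measurement error with variance σ².  Estimation
proceeds in four steps, all pooling observations across subjects:

1. **Mean.**  μ̂ by a 1-D local linear kernel smoother of all (T_ij, Y_ij);
   the bandwidth is selected by generalized cross-validation over a
   log-spaced candidate grid.
2. **Covariance.**  Raw covariances
   G_i(T_ij, T_il) = (Y_ij − μ̂(T_ij))(Y_il − μ̂(T_il)) with j ≠ l have
   expectation G(s,t); same-index products target G(t,t) + σ².  The
   off-diagonal products feed a 2-D local planar smoother for Ĝ(s,t)
   (output symmetrised).  The diagonal G̃(t) is re-estimated by a smoother
   in rotated coordinates u = (s+t)/√2, v = (t−s)/√2 — locally linear along
   the diagonal, quadratic across it, evaluated at v = 0.  A 1-D smoother
   V̂(t) of the same-index products estimates G(t,t) + σ², and
   σ̂² = max(0, trapezoid-mean over the middle half [10.5, 31.5] w of
   V̂ − G̃); the middle half avoids boundary bias, and a negative average
   clamps to zero with a warning.
3. **Eigensystem.**  With W the diagonal trapezoid-weight matrix of the
   51-point working grid, the symmetric matrix W^{1/2} Ĝ W^{1/2} is
   diagonalised; eigenvectors are mapped back through W^{−1/2}, giving
   eigenfunctions orthonormal in the quadrature inner product.  Negative
   eigenvalues (smoothing can produce indefinite surfaces) are truncated
   and excluded from the variance-explained denominator.  Signs follow a
   fixed convention (non-negative integral; ties broken at the last grid
   node) so score signs are reproducible.  K is the smallest component
   count whose cumulative fraction of variance explained reaches 0.99.
4. **Scores by conditional expectation.**  Numerical integration is
   hopeless with 3–5 points per curve; under joint Gaussianity the best
   predictor of ξ_ik given the subject's observation vector Ỹ_i is

       ξ̂_ik = λ̂_k φ̂_ik' Σ̂_Yi⁻¹ (Ỹ_i − μ̂_i),

   and the trajectory estimate is X̂_iK(t) = μ̂(t) + Σ_k ξ̂_ik φ̂_k(t).
   Σ̂_Yi is assembled from the **positive-part eigenexpansion** of Ĝ plus
   σ̂² on the diagonal rather than by direct bilinear interpolation of the
   raw smoothed surface: the raw surface can be indefinite, and an
   indefinite Σ̂_Yi turns the conditional-expectation weights into noise
   amplifiers.  A ridge-jitter ladder (1e-8·mean-diagonal, escalating
   tenfold to 1e-4) guards nearly coincident visit times, with a final
   eigenvalue-clipping fallback.

### Confidence bands

The score-prediction error ξ̂_K,i − ξ_K,i has covariance
Ω_K = Λ − H Σ_Yi⁻¹ H' with H = (λ_1 φ_i1, …, λ_K φ_iK)'.  The variance of
the curve estimate at t is φ_{K,t}' Ω̂_K φ_{K,t}, giving pointwise
(1−α) intervals with multiplier Φ⁻¹(1−α/2) and simultaneous whole-curve
bands with the Scheffé-type multiplier √χ²_{K,1−α}.  For K = 1 the two
coincide.  The simultaneous band is conservative; in the plug-in experiment
below its whole-curve coverage is ~97% at the nominal 95%.

## The logistic mixed-effects comparator

The parametric benchmark is a logistic growth curve with a baseline offset,

    W_i(t) = L_i / (1 + exp(−k (t − t₀))) + c_i + e_ij,

where the magnitude L_i and baseline c_i are correlated Gaussian random
effects, the steepness k is a fixed effect, and the inflection t₀ is pinned
at 30 weeks (the inflection of the mean weight curve; configurable).  For
fixed k the model is linear in (L_i, c_i), so the marginal likelihood is an
exact linear-mixed-model likelihood; the population means are concentrated
out by generalised least squares and the remaining five parameters (log k,
the log-Cholesky factor of the random-effect covariance with the
off-diagonal scaled by the second diagonal, log σ) are maximised by
L-BFGS-B with variance floors of 1e-8 keeping every per-subject covariance
well conditioned.  The scaled-Cholesky parametrisation matters for
degenerate data: when the variance floors activate, every entry of the
random-effect covariance collapses with them, leaving no log-singular flat
direction.  Per-subject (L_i, c_i) are empirical-Bayes posterior modes.

Model fit is compared by the mean squared error of fitted versus observed
weights pooled over all visits, and by the percent reduction in residual
variance, 100·(1 − var_FPCA / var_NLME).  Because an estimated logistic can
only dilate and shift one shape, it cannot follow women who lose weight in
early pregnancy; the data-driven eigenbasis can, which is what the
mixed-cohort experiment demonstrates.

## Weight-change outcomes and regression

Four responses per subject: G = max{W_H, W_C} − W_0 and
LG = log(max{W_H, W_C}/W_0) from raw records (if one of W_H/W_C is missing
the other stands in; both missing flags the outcome unusable), and G′, LG′
computed the same way from the reconstructed trajectory evaluated at t = 0
and at the subject's own GA at birth (linear interpolation on the grid).
Each response is regressed by OLS on prepregnancy BMI alone or together
with the pregnancy-averaged caloric intake and physical-activity index;
the two 24-hour-recall instruments are always fitted as separate strata,
never pooled.  R² is unadjusted and RMSE uses n in the denominator (both
configurable conventions, chosen to match how such tables are usually
printed).  No multiple-testing correction is applied; the report prints raw
quantities.

Because the reconstruction is a conditional expectation, it is *shrunken*:
regressing G′ on G gives a slope strictly between 0 and 1, and outcome
regressions on covariates that drive the weight change are attenuated by
the non-recovered variance fraction.  With a realistic weight-change spread
this attenuation is negligible (see design notes), but it is a structural
property of conditional-expectation reconstruction, not a bug.

## The synthetic cohort generator

No cohort data ship with the package; the generator emulates the study
design so every stage is testable.

* **Truth objects** hold a dense-grid mean, orthonormal eigenfunctions
  (Gram–Schmidt under trapezoid quadrature), eigenvalues, noise sd,
  reporting-bias parameters and an optional BMI link.
* **Visit design**: windows A/B/C as above, GA at birth from a truncated
  normal (mean 39.5 w, sd 1.1 w) on [37, 42]; per-window missingness
  (defaults 15/10/10%) and a 25% late-recruitment rate (no A visit).
  Visit times are uniform within windows.  W_C always precedes the GA at
  birth by construction.
* **Self-report bias**: W0 under-reported by N(−1, 1) kg and WH
  over-reported by N(+1, 1) kg by default, so directly computed gains
  overestimate true gains — the generator reproduces that known artefact.
* **Application-scale truth** (`make_paper_like_truth`): logistic mean from
  62 to ~76.7 kg with inflection at week 30; three eigenfunctions (level,
  early-vs-late gain contrast, mid-vs-late contrast) with variance
  fractions 95.7/2.8/1.1%; the eigenvalue scale is set so the implied
  prepregnancy-weight sd is ~12 kg.  With the BMI link active, BMI is drawn
  log-normal (median 23 kg/m², log-sd 0.17), height normal (1.64 ± 0.065 m),
  and the first two scores are *solved* per subject so that
  X(0) = BMI·height² and log(X(ga)/X(0)) = b0 + b1·BMI + η hold exactly
  (b1 = −0.012 per kg/m² by default).  This departs from independent
  N(0, λ_k) scores — deliberately, so the generative regression coefficient
  is exact rather than an attenuated by-product of the construction.
  Without the link, scores are independent N(0, λ_k).
* **Experiment-scale truth** (`make_kl_truth`): same shapes, independent
  scores, no bias, eigenvalues (40, 12, 6) kg²·w and σ = 1 kg.  The scale
  is deliberately moderate: the sampling noise of raw covariances grows
  with the square of the covariance magnitude, and under a
  one-visit-per-trimester design the mid-domain diagonal strip contains no
  off-diagonal pairs at all, so at the application's ~135 kg² pointwise
  variance the noise variance σ² is only weakly identifiable.  Recovery
  experiments therefore run at a scale where their targets are identifiable;
  what passing them shows is that the estimators are correct and calibrated,
  not that σ² could be pinned to ±20% in a real cohort of this design.
* **Deviant subpopulation** (`make_early_loss_truth`): a broad weight loss
  centred mid-pregnancy with partial late regain — a shape outside any
  single logistic family.
* **Logistic cohorts** (`simulate_logistic_cohort`): exact Eq-style
  logistic curves with Gaussian (L_i, c_i), used as the comparator's own
  generative ground truth.

What the generator does **not** emulate: item-level diet-recall or
activity-questionnaire data (only their subject-level averages, drawn as
plain Gaussians uncorrelated with weight), correlated visit missingness,
BMI-dependent measurement error, pregnancies ending before 37 weeks
(preterm subjects are only relevant to the inclusion-filter tests, which
construct them directly), or twin pregnancies.  Passing tests on this
generator shows the estimators do what their theory promises under the
stated design; it cannot show how they behave under real-world
departures from Gaussianity or informative missingness.

## Numerical choices

* Working grid: 51 equally spaced points on [0, 42] weeks; trapezoid
  quadrature throughout; 201 points for the closed-form Brownian-covariance
  check; truth objects use a 421-point grid (0.1 w).
* Kernels: Gaussian default (infinite support rarely needs the boundary
  rule), Epanechnikov available.  Where a local design is rank deficient
  the bandwidth widens geometrically (×1.5, at most 5 times), else an error.
* Surface bandwidth: 4 weeks by default — wide enough to bridge the gaps
  the trimester schedule leaves between pair clusters while keeping the
  small-variance-fraction components that the 99% rule must see.  On
  moderate-variance cohorts (covariance of a few kg²) the eigenvalue tail
  is dominated by sampling noise rather than attenuation and a wider 6.5 w
  setting stabilises component selection; the recovery experiments use it
  explicitly.
* Rotated-diagonal smoother: along-diagonal bandwidth 8 w, perpendicular
  6 w.  The perpendicular width is deliberately large because the design
  leaves the near-diagonal strip empty mid-domain; curvature across the
  diagonal must be borrowed from pairs further out.  These defaults come
  from bias–variance measurements: noiseless large-sample runs isolate the
  quadratic-model bias (which grows with the perpendicular bandwidth), and
  seeded replications measure the sampling sd (which shrinks with it).
* σ̂² at application scale is reported but should not be over-read; see the
  generator notes above.  The score machinery degrades gracefully when σ̂²
  is off because the level component dominates Σ_Yi.
* NLME: start values k = 0.15/w, baseline from the earliest weights,
  magnitude from the mean gain; L-BFGS-B with ftol 1e-12, at most 500
  iterations; deterministic given data and starts.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give identical cohorts and
  identical pipeline outputs.

## Design notes on the regression experiment

The LG′ ~ BMI recovery experiment uses `make_paper_like_truth(lg_sd=0.095)`:
the LG spread is set directly (total-gain sd ≈ 6.5 kg, a realistic
population spread) instead of being derived from the printed variance
fractions, which would imply a gain spread so tight that
conditional-expectation shrinkage attenuates the slope by several standard
errors.  The slope-recovery check reconstructs trajectories under the
true-model plug-in (exactly as the band-coverage experiment does): with a
*fitted* model at desk-scale n, cohort-level correlated estimation error
roughly doubles the slope's real sampling spread relative to the naive OLS
standard error, so a ±2-naive-SE criterion undercovers even for an unbiased
estimator — a caveat worth remembering when reading regression tables built
on reconstructed outcomes.  The R²-ordering check (trajectory-based LG′
explains more variance than the bias-contaminated raw G) holds end-to-end
with fitted models as well.

## Known limitations

* σ² is structurally hard to identify under the one-visit-per-trimester
  design at realistic weight-variance scales (empty near-diagonal strip).
* The FVE-at-0.99 rule interacts with the surface bandwidth: heavy
  smoothing attenuates small components (K too small), light smoothing
  admits noise modes (K too large).  The defaults balance this for the
  scales the package targets; new designs warrant a sensitivity check.
* Bands are plug-in: they ignore the sampling error of μ̂, φ̂, λ̂, σ̂²
  themselves; no resampling correction is applied.
* The comparator is fit by exact marginal ML, which is only possible
  because the logistic model is conditionally linear in its random effects;
  a comparator with a random steepness would need genuine nonlinear
  mixed-effects machinery.
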