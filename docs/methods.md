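# Methods

This note documents the estimators implemented in `robustpls`, the
defaults and why they were chosen, the synthetic data the package is
validated on, and the numerical decisions a user should know about.

## Linear PLS1 (`robustpls.pls`)

NIPALS with sequential deflation for a univariate response.  Per
component: `w ∝ Xᵀy` (unit norm), `v = Xw` normalized, `p = Xᵀv`,
`q = yᵀv`, then `X ← X − vpᵀ`, `y ← y − vq`.  For a univariate response
the inner power loop converges in a single pass, so it is evaluated
directly; the nominal tolerance (1e-4) and iteration cap are honored
trivially.  The regression vector is `b = W (PᵀW)⁻¹ q` on centered data.
Signs are fixed by making the largest-magnitude element of each weight
vector positive, so extracted directions are identical across platforms.
Columns are centered but not autoscaled by default (spectral practice).
A degenerate weight vector (norm < 1e-12) stops extraction early with a
logged warning and a model with fewer components.

Observation weights enter by weighted centering and scaling rows by
`sqrt(w)`, which makes the criterion the weighted residual sum of squares
and removes zero-weight rows exactly (verified against physical deletion
to 1e-10).  Correctness oracles: full-component PLS equals OLS; the
sequential fit equals the independent Krylov-space closed form
`b = R(RᵀXᵀXR)⁻¹RᵀXᵀy`, `R = [s, Gs, G²s, …]`, `s = Xᵀy`.

## Robust weights and scales (`robustpls.robust`)

Weight families: fair `w(z) = 1/(1+|z/c|)²` (default, c = 4 for both the
residual and the leverage weight — the standard PRM choice) and Huber
`w(z) = min(1, c/|z|)`.  The residual weight standardizes by the MAD scale
(raw MAD × 1.4826); the leverage weight uses the Euclidean distance of
each score row to the spatial median (Weiszfeld iteration, tol 1e-8, 200
iterations), standardized by the median distance.  A leverage weight below
0.01 marks a suspected high-leverage observation.

Scale estimators:

* `mad_scale` — 1.4826 × raw MAD (consistent at the normal model).
* `lts_scale` — trimmed rms of the h smallest squared residuals,
  h = ⌊(n+l+1)/2⌋ by default, divided by the truncated-normal consistency
  factor `sqrt(1 − 2 q φ(q)/α)`, α = h/n, q = Φ⁻¹((1+α)/2).  Consistent
  within 5% at n = 10⁴ (tested).
* `lms_scale` — `1.4826 (1 + 5/(n−p)) median|r|`.

**PRM** iterates: weighted PLS fit → residuals on all (unscaled) rows →
MAD scale → new generalized weights `w = wʳ·wˣ` → refit, until the
relative coefficient change drops below 1e-6 or 30 iterations.
Initial weights come from median-centered responses and raw-predictor
distances.  The weighted objective Σwf² is monitored; an iteration that
increases it is rolled back and the previous iterate returned.  The
leverage weight uses scores of the *unscaled* rows (`(x − x̄)W*`), so
downweighted observations are not artificially shrunk toward the center.
On the sine study the linear IRLS legitimately never meets the coefficient
tolerance (a line cannot represent a sine, so the weights keep adjusting);
the loop then returns the best iterate with a logged warning.

**PRMM** freezes the LTS scale of the PRM residuals and continues the
M-iterations with that fixed scale.  The returned estimate is guaranteed
not to exceed the stage-1 weighted objective evaluated at the LTS scale
(if the iteration ends higher, the stage-1 estimate is returned), the
defining inequality of the MM construction.  Breakdown behavior: with 40%
gross symmetric response contamination at n = 100 the slope error stays
below 20% of the true coefficient norm in all tested replicates.

**PRGM6** takes the PRMM fit as the high-efficiency initial estimator
(an LTS elemental-subset fit on the score space is available via
`gm6_initial="lts"`: 500 seeded subsets plus two concentration steps).
Leverage weights are `wᵢ = min(1, χ²₀.₉₅,l / RM²ᵢ)` from MVE-based robust
Mahalanobis distances on the score matrix; the residual scale is the LMS
plug-in; the final coefficients are one Newton–Raphson step
`a = a₀ + (VᵀBV)⁻¹ Vᵀ[σ̂ wᵢ ψ(rᵢ/(σ̂ wᵢ))]` with Huber ψ (c = 1.345) and
`B = diag(ψ′)`.  A singular `VᵀBV` falls back to a ridge-regularized
solve with a warning.

## MVE and the DRGP diagnostic (`robustpls.diagnostics`)

`mve_fit` is resampling MVE: 500 seeded elemental (l+1)-subsets, each
inflated to cover h = ⌊(n+l+1)/2⌋ points; the minimum-volume candidate
wins.  The reported location/shape are the classical moments of the h
points covered by the winning ellipsoid — the raw elemental covariance is
far too anisotropic to use directly (measured shape eigenvalues spanning
0.45–1.48 on N(0, I₃) data) — rescaled by `median(d²)/χ²₀.₅,l` for
consistency.  Distances are therefore exactly affine invariant for a
matched seed (tested to 1e-8).  A one-step χ²₀.₉₇₅ reweighting was
evaluated and found outcome-neutral for the diagnostic, so it is not
applied.

The DRGP run: screening cut-off `median(RM²) + 3·MAD(RM²)` with the *raw*
MAD; confirmation cut-off `median(p*) + c·MAD(p*)/0.6475` (c = 3 by
default, 2 available).  The two deliberately different MAD scalings follow
the printed forms of the procedure and are exposed as separate helpers.
Below-cut-off suspects are put back one at a time, smallest potential
first, recomputing potentials and cut-off after each return — a
deterministic, conservative order.  If screening flags so many rows that
`V_RᵀV_R` would become singular, only the most distant `n − l − 1`
suspects are kept, with a warning.

Calibration: on clean N(0, I₃) scores (n = 100) the procedure flags a
median of 3% of rows; because the potential distribution is right-skewed,
its top order statistics exceed a median+MAD cut-off in almost every
sample, so a small false-positive rate on perfectly clean data is
intrinsic to this family of rules (6–11% in roughly a quarter of
replicates).  A 10σ leverage row is flagged in 100% of replicates.

## Kernel methods (`robustpls.kernel`)

Gaussian kernel `K_ij = exp(−‖xᵢ−xⱼ‖²/σ²)` with `σ²` defaulting to the
total (non-robust) variance of the training predictors — the sum of
per-column sample variances, reducing to the scalar variance for one
predictor.  Kernel NIPALS extracts orthonormal scores from the
double-centered Gram matrix with `(I − vvᵀ)` deflation of both K and y;
prediction uses the dual form `ŷ_v = K_v U (VᵀKU)⁻¹ Vᵀy` with the test
Gram matrix centered against the training rows.  With the linear kernel
the whole pipeline reproduces linear PLS1 to 1e-6 in fitted and predicted
values — the module's master oracle.  The identity `K U (VᵀKU)⁻¹ = V`
holds exactly for orthonormal scores, which gives an exact out-of-sample
score transform used by the diagnostics.

Observation weighting uses `K̆ = Ω K Ω`: KPRM sets `Ω = diag(√wᵢ)` so the
weighted objective is Σwᵢfᵢ²; KPDRGP uses 0/1 weights.  Centering
statistics are computed with the same weights (the printed uniform
double-centering is the equal-weight special case), which makes a 0/1
weight matrix exactly equivalent to removing the zero rows before
fitting (tested to 1e-10).

**KPDRGP** normalizes the response to zero mean and unit variance over
the surviving rows (inverted at prediction), fits kernel PLS, and runs
the DRGP diagnostic on the per-observation pair of X-side and y-side
score coordinates.  The y-side score matrix U adds exactly one dimension
beyond span(V) — every U column is a deflation of y inside span{y, V} —
so the pair space is represented full-rank, and by affine invariance of
the Mahalanobis distance without loss, as the l+1 columns
`[V, y_normalized]`.  This inclusion of the response coordinate is what
lets a leverage diagnostic see vertical outliers, which are invisible in
the X-side kernel geometry alone (their x values are clean).  Confirmed
rows get Ω = 0 and the model is refit once; optional additional
diagnose–refit cycles (`max_cycles > 1`) re-diagnose *all* rows against
the refitted model, scoring deleted rows as test points, and flags are
monotone.  The default is a single pass: iterating the diagnosis on a
curved score manifold peels boundary rows indefinitely (each deletion
makes the next boundary row the extreme), which measurably degrades clean
data fits while adding nothing on contaminated data.

**Number of components.**  Kernel fits of the n = 41 sine study default to
l = 3.  Three components capture the ~1.2 sine periods; with five or more,
the score rows of a one-predictor problem trace a strongly curved manifold
whose end points dominate any fitted ellipsoid, and the diagnostic then
flags curve boundaries instead of outliers (measured: median 2/7 true
outliers recovered at l = 5 versus 7/7 at l = 3).  Linear fits on the sine
are capped at l = min(n−1, m) = 1 automatically.

## Metrics (`robustpls.metrics`)

RMSE = √(Σe²/n); Bias = ē; SE = SEP = √(Σ(e−ē)²/(n−1)); R² = squared
Pearson correlation of measured and predicted (the chemometrics
convention; 1 − SSE/SST available as `r2_definition="explained"`);
RPD = sd(y)/SEP.  Optional weights give the weighted analogues with an
effective-sample-size correction.  Benchmark training metrics use each
method's final observation weights — a robust method is scored on the
observations it retained — which is the only convention under which the
robust methods' training rows are internally consistent; test metrics are
always unweighted.  Replicates are aggregated by medians, robust to an
occasional non-converged fit.

## Synthetic data (`robustpls.simulate`)

*Sine study*: 41 training x ~ Uniform[0, 10] (sorted), y = sin(−3/4·x) +
N(0, 0.05²); 7 vertical outliers at fixed 1-based positions
{10, 12, 18, 19, 28, 33, 36} of the sorted set, with magnitudes drawn
from Uniform(1, 2) — the sine has unit amplitude, so such shifts are
unambiguous outliers — directed away from the curve.  The test set is an
equally spaced 101-point grid carrying the same noise model (the noiseless
truth is also exposed).  Test metrics are computed against the noisy test
response.

*NIR-like spectra*: sums of Gaussian absorption bands whose amplitudes
follow a latent concentration (a bounded percentage) through a mixture of
a linear and a saturating link, degraded by multiplicative scatter and a
smooth random quadratic baseline, with optional contamination of the
response (gross shifts) and of the spectra (inflation/spikes).  The
generator emulates the shape and nuisance structure of real oil-fruit
mesocarp spectra (n ≈ 960, m ≈ 489) but makes no attempt to reproduce a
real instrument's noise physics or band assignments — results on it show
that the estimators behave as designed under known contamination, not
that any particular real dataset would yield the same numbers.

## Known limitations

* The DRGP family of cut-offs (median + c·MAD on skewed leverage
  statistics) has a small intrinsic false-positive rate on perfectly
  clean data; on curved score manifolds the false positives concentrate
  at the boundary of the predictor range.
* The kernel score geometry of a one-predictor problem is a curve, which
  is the hardest case for ellipsoid-based screening; higher-dimensional
  predictor spaces (real spectra) are closer to the elliptical ideal.
* KPRM's leverage weight operates on dual-transform scores of all rows;
  with extreme weight collapse (nearly all weights ≈ 0) the transform can
  become ill-conditioned.  The IRLS guards weights at 1e-12 and stops on
  an objective increase.
* Multivariate-response PLS2, SIMPLS, cross-validated component selection
  and spectral pre-processing (SNV/MSC/derivatives) are out of scope.
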