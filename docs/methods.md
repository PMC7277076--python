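# Methods

## Generating model

The synthetic-data module emulates a survey of past-year gamers who
answer the 34-item ordinal checklist, the nine binary DSM-5 IGD
criteria, a 20-item Internet-addiction (IA) scale (range 20–100), a
10-item depression scale (range 0–30), and three behavioural items
(weekly gameplay frequency, monthly expenditure band, preferred
device). One standard-normal general severity factor `G` drives
everything:

* subconstruct scores `F_j = γ_j G + δ_j` with `Var(δ_j) = 1 − γ_j²`,
  so every factor is marginally standard normal;
* latent item responses `y* = λ_i F_j + ε_i`, discretized at per-item
  thresholds `(τ1, τ2)` into codes {0, 1, 2};
* DSM-5 criterion k endorsed iff `a_k G + noise > c_k`;
* continuous/ordinal criteria are affine transforms (clipped to their
  scale ranges) or normal-quantile discretizations of `b G + noise`.

Defaults are the published study conditions. The λ and γ defaults are
the published standardized loadings of the 34-item model
(`igdscreen.reference`). Item thresholds default to `(−0.25, 0.84)` —
right-skewed category frequencies of roughly (40%, 40%, 20%),
plausible for symptom items; the source reports no item-level
frequencies, so these are declared defaults, not estimates, and are
fully configurable. DSM discriminations are 0.70 with a common
cutpoint 0.8575, calibrated once (Gauss–Hermite quadrature over `G` of
the binomial tail) so that P(DSM sum ≥ 5) = 0.129, the study's
reference prevalence; the resulting KR-20 of the nine criteria is
≈ 0.78, inside the plausible band around the study's 0.74.

Criterion targets (sum-score correlations 0.45 with IA, 0.40 with
gameplay frequency, 0.28 with depression) are met by setting the
criterion loading `b = target / r_SG` where `r_SG = 0.9391` is the
model-implied correlation of the 27-item sum with `G` under the
default configuration (frozen from a one-off 4×10⁵-replicate
calibration), additionally divided by the discretization attenuation
0.8277 for the four-band frequency item. Criteria are driven by `G`
only, not by the first-order disturbances — the simplest structure
consistent with the published sum-score correlations. Frequency bands
use marginal probabilities (0.233, 0.086, 0.086, 0.595): the published
outer shares, with the unreported middle mass split evenly.
Expenditure uses (0.677, 0.209, 0.114) and a weak severity loading of
0.25 (the study reports only a significant group difference, no
effect size). Device is independent of severity with the published
shares renormalized (they print to 100.1%).

Randomness derives from one root `SeedSequence` per configuration
seed with fixed substreams (0 latent factors, 1 item responses,
2 criteria), so each component is reproducible in isolation.

What the generator does **not** emulate: missing responses,
differential item functioning, longitudinal structure, non-normal
latent traits, or the real (unpublished) item response frequencies.
Passing tests therefore demonstrate correctness of the estimators and
decision rules under the assumed model, not agreement with the
original sample's data-dependent statistics.

## Polychoric estimation

Two-stage: thresholds fixed at normal quantiles of the empirical
cumulative proportions, then each pair's latent correlation by 1-D
likelihood maximization over ρ ∈ [−0.999, 0.999] (bounded Brent,
xatol 1e−6; endpoints checked explicitly so near-singular tables clip
at the bound). Bivariate-normal rectangle probabilities use the
Owen's-T closed form of the CDF (vectorized, cross-checked against
`scipy.stats.multivariate_normal` at 1e−10); cell probabilities are
floored at 1e−12 before logs. Empty categories collapse toward the
nearest non-empty neighbour with a logged warning; constant items are
an error. Each estimate carries an asymptotic variance from the
observed information (central second difference, h = 1e−4), stored as
the inverse variance of √n·(ρ̂ − ρ) to serve as the DWLS weight.

## Factor model estimation and fit

The implied correlation of the second-order model is
`σ_ik = λ_i λ_k` within a subconstruct and `λ_i λ_k γ_j γ_l` across
(all factors standardized, Φ = γγᵀ + diag(1 − γ²)). The one-factor
comparison model is the γ ≡ 1 submodel; the independence baseline has
no parameters. Estimation minimizes the (diagonally) weighted least
squares discrepancy on the strict lower triangle with L-BFGS-B
(start 0.7, bounds ±0.999, max 500 iterations); `uls` (unit weights)
is the fallback whenever no weight matrix is available. The sample
matrix is repaired to positive semidefinite by eigenvalue clipping at
1e−6 (logged) when needed.

χ² = (n−1)·F_min without any mean-and-variance adjustment of the test
statistic; CFI/TLI use the independence baseline with the usual
max-protection, RMSEA = √(max(χ²−df, 0)/(df·(n−1))) with a best-effort
noncentral-χ² 90% interval, and SRMR is the root mean square
correlation residual. Because the adjustment is not replicated, these
indices are comparable in spirit, not numerically, to full WLSMV
output — which is why validation rests on self-consistency (fitting a
model-implied matrix returns the model to 1e−4), parameter recovery
(MAE of λ̂, γ̂ < 0.05 at n = 2000; bias < 0.02 at n = 5000), and model
ordering (the one-factor discrepancy strictly exceeds the second-order
discrepancy on every simulated dataset), not on matching printed
index values. Degrees of freedom are `p(p−1)/2 − free parameters`
(correlation-only fitting), which reproduces the published 518/527/315
for the 34-item second-order, 34-item one-factor and 27-item
second-order models.

## Item reduction and scoring

Within each subconstruct the k = 3 items with the highest standardized
loadings are retained, ties broken by questionnaire order (logged).
Loadings are compared at full floating precision; on the published
2-dp values the selection is identical. Sum scores are plain item
sums; rows with missing scale items are refused by the scorer itself
and handled listwise by the pipeline's CSV reader.

## Reliability and validity statistics

Cronbach's α uses sample (ddof = 1) variances throughout. KR-20 uses
`Σ p(1−p)` from the item means over the sample total variance — the
conventional form; note it equals 1 for identical items only
asymptotically. The group-contrast t test is the pooled (Student)
form because the published df equals n − 2 (Welch available behind a
flag); Mann–Whitney U is reported in both orientations because the
published convention is unstated; the chi-square independence test
drops zero-margin rows/columns with a warning. p-values come from the
standard reference distributions. Subscale–criterion correlations are
Pearson on sum scores.

## Screening and cutoff selection

Rates are percentages; κ uses marginal-product chance agreement; the
DOR is the cross-product with Haldane's +0.5 on all cells iff any
cell is zero. AUC is the trapezoid over all distinct thresholds and
is tested to equal the rank-pair statistic to 1e−12. Reported
percentages are rounded half-up to 1 dp and κ/J to 2 dp, matching the
published table convention (half-up, not banker's: 41/80 must print
51.3). The rounding helper pre-quantizes 8 digits below the target to
absorb binary floating-point noise in ratios of small integers.

Step 2 of the selection rule compares κ *after* rounding to 2
decimals: on the published scan the unrounded κ at the two finalists
differs in the third decimal (0.5001 vs 0.5025) and only the rounded
values produce the published two-way tie, which the sensitivity
tie-break then resolves. The 75% screen is strict (the published row
with specificity 73.0 is excluded). An empty candidate set is an
explicit "no admissible cutoff" result, not an error.

The seven integer 2×2 tables behind the published per-cutoff rows are
re-derived, not trusted: `reconstruct_confusion_tables` searches all
tables with margins 60/404 whose four rate columns round to the
printed values and asserts uniqueness. Two documented inconsistencies
in the source are excluded from reproduction: the printed DOR column
(e.g. 26.62 at cutoff 20 versus 26.05 from the unique reconstructed
counts; the original software's internal DOR computation is unknown)
and the cutoff-17 Youden cell (0.69 printed, consistent with
rounded-percentage arithmetic but not with exact counts, 0.6847 → 0.68).

## Problem sizes and numerical choices

Simulation-based tests use n = 464 (the study size) for end-to-end
runs and model-ordering checks, n = 2000 for parameter recovery
(5 seeds), and n = 5000 for calibration sanity bands — sizes at which
sampling error is well inside the asserted tolerances while the whole
suite stays fast. Optimizer tolerances: polychoric xatol 1e−6; CFA
ftol 1e−14 / gtol 1e−8, convergence also accepted at gradient norm
< 1e−6. Degenerate inputs (constant items, single-class references,
zero variances, zero margins) raise informative errors rather than
returning silent zeros.

## Known limitations

* Fit indices are not WLSMV-adjusted and must not be compared
  numerically against software that applies the mean-and-variance
  correction.
* No standard errors or confidence intervals for loadings, κ or AUC.
* Polyserial correlations, full-information ML, missing-data
  mechanisms and measurement invariance are out of scope.
* The synthetic thresholds are conventions; quantities that depend on
  the score distribution (e.g. the simulated optimal cutoff) are not
  comparable to the instrument's published cutoff.
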