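# Methods

## Model

`crlandmark` estimates the Fine–Gray subdistribution hazard model for a
cause-1 event (kidney failure in the motivating application) in the
presence of a competing cause-2 event (death). With residual time T from a
landmark origin, cause δ ∈ {0 censored, 1, 2} and covariates x, the model
is λ₁(t|x) = λ₁₀(t)·exp(x'β) for the hazard of the improper cause-1
distribution, so the predicted cumulative incidence is
F₁(t|x) = 1 − exp(−Λ₁₀(t)·exp((x − x̄)'β)).

Estimation maximizes the weighted partial likelihood in which cause-2
subjects remain in the cause-1 risk set after their event with weights
w_j(t) = Ĝ(t⁻)/Ĝ(T_j⁻), Ĝ being the Kaplan–Meier estimate of the censoring
survival function computed on the analysis data (censoring = event). The
weight convention uses left limits, keeping weights in [0, 1] and
non-increasing. Ties are handled by the Breslow approximation, matching the
Breslow-type baseline

Λ̂₁₀(t) = Σ_{s_k ≤ t} d₁_k / Σ_j w_j(s_k)·exp((x_j − x̄)'β̂),

anchored at the training covariate mean x̄ (the model centers covariates
internally, so adding a constant to any covariate leaves all predicted
CIFs unchanged).

### Forward–backward scan

Every denominator of the weighted partial likelihood splits into a suffix
sum over the conventional risk set {j : T_j ≥ t} and a prefix sum over
weighted cause-2 contributions {j : δ_j = 2, T_j < t} scaled by Ĝ(t⁻).
After one sort, both are cumulative sums, so the log-likelihood and score
cost O(np) and the full Hessian O(np²) — no O(n²) risk-set loops. A direct
double-loop reference implementation is retained for validation and is
checked to 1e−8 agreement in the test suite.

### Newton solver

Unpenalized fits use Newton–Raphson with step-halving, gradient max-norm
tolerance 1e−8 and at most 50 iterations. Two numerical guards matter in
practice: the line-search acceptance uses a relative slack of ~1e3·eps·|ℓ|
(the log-likelihood is a sum of O(n) terms and recomputation jitters at
that scale), and a proposed Newton step below 1e−11 in max-norm is treated
as numerical convergence. Coefficients beyond ±20 trigger a separation
warning and are capped. Standard errors are model-based Wald (inverse
observed information); they ignore the estimation of Ĝ, which in the
simulations keeps 95% interval coverage within [0.90, 0.99] — a robust
(crr-style) variance is deliberately out of scope.

## Penalized selection

The MCP objective on the mean log-likelihood scale, with internally
standardized covariates, is −ℓ(β)/n + Σ pf_j·p_{λ,γ}(|β_j|). Cyclic
coordinate descent uses the exact univariate MCP minimizer of the local
quadratic surrogate built from the per-coordinate score and information
(each O(n) via the scan), active-set cycling, and a 1e−7 tolerance on the
maximum coefficient change. The path is warm-started from λ_max (the
smallest penalty zeroing all penalized coordinates, computed from the score
at the null/adjuster-only fit) down to 0.001·λ_max over 50 log-spaced
points by default; γ defaults to 3.0. When a coordinate's surrogate
curvature falls below 1/γ the univariate problem is non-convex and the
update compares the two stationary candidates (0 and the unpenalized step)
by objective value.

Cross-validation folds are subject-level; each candidate λ is scored by the
out-of-fold 10-year IPCW time-dependent AUROC of the fold model's linear
predictor, ties are broken toward the larger (sparser) λ, and the selected
support is refit unpenalized. Adjusters can be protected from the penalty
via a zero penalty factor.

## Evaluation

At horizon h: cases are cause-1 events by h; controls are subjects
event-free beyond h *or* with a competing event by h (a death can never
become a case). IPCW weights are 1/Ĝ(T⁻) for cases and cause-2 controls
and 1/Ĝ(h) for event-free controls. The AUROC is the weighted Mann–Whitney
statistic (ties in score count ½); the AUPRC integrates the weighted
precision over recall step-wise (no linear interpolation of precision).
The Brier score is the IPCW-weighted mean squared difference between the
cause-1 indicator and F̂₁(h|x). With no censoring and no competing events
these all reduce to their classical binary forms, which the tests exploit.

Calibration regresses jackknife pseudo-observations of the Aalen–Johansen
cause-1 CIF on predicted risk (OLS, intercept included); slope 1 indicates
perfect calibration and slope > 1 risk underestimation. The leave-one-out
Aalen–Johansen estimates are computed exactly in O(n log n) by decomposing
each F̂^(−i)(h) into a prefix sum with at-risk counts reduced by one, an
own-time correction, and a shared suffix recursion; the decomposition is
algebraically identical to naive re-estimation (validated against a naive
jackknife oracle), and the censoring-free case short-circuits to the exact
identity PO_i = 1{T_i ≤ h, δ_i = 1}. Bootstrap intervals are percentile
intervals over subject-level resamples with a fixed seed.

## Transport and recalibration

A model moves to a target cohort (or later landmark) by freezing β,
computing the source linear predictor on target subjects as a fixed offset
(coefficient exactly 1 — slope recalibration is deliberately excluded), and
re-estimating the baseline cumulative hazard under either the Fine–Gray
weighting or the cause-specific Cox convention (competing events censored;
the two coincide when no competing events exist). The baseline is anchored
at the target-cohort mean of the predictors. Because recalibration is a
monotone transform of the linear predictor, discrimination is invariant;
only absolute risk and hence calibration change. The refit-vs-recalibrate
harness fits both arms on a later landmark's training split and evaluates
both on its test split across horizons.

## Benchmark equations

Risk equations are JSON configs (inputs with scale/log/centering
transforms, coefficients, per-horizon baseline survival anchors), evaluated
as risk(h|x) = 1 − S₀(h)^exp(Σ c_j(g_j(x_j) − center_j)). The 4-variable
KFRE ships with its published coefficients and 2-/5-year baseline
survivals (North American anchors by default; the non-North-American
recalibrated anchors are a flag). An unmeasured urine
albumin-to-creatinine ratio defaults to 7.5 mg/g (a median healthy value)
before the log transform. The RECODe-style file is a clearly labelled
synthetic stand-in: the structure mirrors the published equation but the
coefficients are placeholders, because the audited values are not
distributed with this package; users must supply them before substantive
use. Equations plug into the same baseline-recalibration machinery as
fitted models.

## Synthetic cohorts

The generator uses the indirect-CIF design that makes β₁ *exactly* the
subdistribution log-hazard ratio:

F₁(t|x) = 1 − [1 − p·(1 − e^{−t/τ})]^{exp(x'β₁)},

with p (`p_mass`) the asymptotic cause-1 incidence at x = 0 and τ
(`time_scale`) a time-axis stretch. Cause assignment is Bernoulli with
P(cause 1|x) = F₁(∞|x); cause-1 times invert the conditional CIF; cause-2
times are exponential with rate `death_rate`·exp(x'β₂); censoring is
exponential truncated at an administrative horizon. `lp1_offset` shifts
the baseline hazard on the log scale (e.g., log 2 doubles it) for
transport experiments, and `simulate_from_model` draws records whose
cause-1 process is a fitted model's own CIF, for calibration
self-consistency checks.

Defaults follow the canonical unit-scale design (τ = 1, unit death rate)
so the closed form above is directly testable. The study pipeline instead
emulates a diabetes-cohort structure: τ = 8 y, p = 0.10, death rate
0.05/y, administrative censoring at 22 y, giving roughly 8% cause-1 and
25% death over follow-up — event fractions large enough to support fitting
at n of a few thousand, an order of magnitude above the motivating
cohort's 1.3% ESRD rate, which desk-scale sample sizes cannot sustain.
Covariates default to a mix of Bernoulli(0.5) flags and standard normals
(every third column binary); the EHR dressing expresses continuous
covariates as noisy repeated labs (plus clinically named eGFR, SBP, HbA1c,
UACR, LDL series), binary ones as dispensation trails, and writes a
kidney-failure code/eGFR trail at cause-1 event dates so the composite
outcome rule reconstructs the simulated outcome. Visits are Poisson
(default 2/year) with a final visit at the exit date, so
censoring-at-last-visit semantics hold.

What the generator does *not* emulate: realistic ICD/CPT vocabularies,
correlated lab panels, informative (MNAR) missingness beyond a single
configurable MAR rule, and measurement processes that depend on disease
severity. Passing tests therefore demonstrate correctness of the
estimators and workflow under a known DGP, not clinical performance on
real EHR data.

## Landmark construction

Composite cause-1 outcome: two coded kidney-failure entries 45–365 days
apart, or two consecutive eGFR measurements < 15 mL/min/1.73 m² at least
45 days apart with no intervening value ≥ 15 ("consecutive" = adjacent in
the chronological series). The event date is the *first* measure of the
qualifying pair — onset rather than confirmation, the conservative choice
for dynamic prediction. Death without prior kidney failure is cause 2 at
the death date; everyone else is censored at their last visit; subjects
with no post-index observations are excluded and logged.

Snapshots use half-open windows (s − w, s]: 2 years for labs (last value
wins), 30 days for medications (a dispensation counts if its exposure
interval — days supply, floored at 30 days — touches the window), full
history for coded conditions. The 70/30 split is drawn once at the first
landmark by subject id and inherited by later landmarks. The missingness
policy is fitted on the first landmark's training split and applied frozen
everywhere (test splits, later landmarks, target cohorts): features over
40% missing are binned at clinical cutoffs (UACR: 30/300 mg/g) with an
explicit missing-indicator category and the first bin as reference;
features at or below 40% get one chained-equations imputation replicate
(scikit-learn's IterativeImputer, 5 round-robin iterations, fixed seed)
and are standardized by training mean/SD. Freezing the schema at the first
landmark is what keeps the coefficient vector portable across landmarks; a
per-landmark refit of data-driven bins would silently change the feature
space.

Univariable screening fits one adjusted logistic regression per candidate
(candidate + age/sex/race-type adjusters) for the outcome "cause-1 event
within the 10-year horizon", including subjects with at least 10 years of
potential follow-up or an earlier event of either cause, and retains
candidates with |logOR| > 0.1 and Wald P < 0.05 (no multiplicity
correction, by design). Binned features are retained if any level passes.
Perfect separation retains the candidate with a warning; a candidate
collinear with the adjusters is assigned logOR 0.

## Interpretation

Shapley attributions are Monte-Carlo permutation estimates on the risk
scale F̂₁(h|x) (a linear-predictor option exists for exact checks), with a
marginal background sample cycled in full permuted passes so the
background-mean sampling error vanishes at multiples of the background
size; 128 samples by default, fixed seed. Operating thresholds come from
the time-dependent ROC grid by Youden's J (max TPR − FPR) or the top-left
criterion (min distance to (0, 1)), ties resolved toward the lower
threshold (higher sensitivity).

## Numerical and design choices, in brief

- Censoring Ĝ is estimated on the evaluation split itself (configurable to
  reuse a training Ĝ via the `G=` argument of the metric functions).
- Deaths before h are controls in the ROC/PR construction — they cannot
  become cases under competing risks.
- CV tie-break toward larger λ; λ grid 50 points to 0.001·λ_max; γ = 3.0.
  These are declared defaults: sensible, not sacred.
- The screening outcome horizon (10 y) matches the CV tuning horizon.
- Degenerate inputs fail loudly: no cause-1 events, rank-deficient designs,
  zero-variance predictions, empty landmark risk sets, unknown schema
  columns and unanchored equation horizons all raise with names attached.
- The pipeline scales its study to n = 4,000 subjects, chosen so the full
  simulate→explain cycle completes in well under a minute while keeping
  hundreds of cause-1 events at the first landmark.

## Known limitations

Single imputation replicate (no MI pooling); no time-varying coefficients
or stratified baselines; model-based (not robust) standard errors; the
RECODe-style benchmark ships synthetic placeholder coefficients; the MAR
missingness mechanism is a single threshold rule on a driver lab; subgroup
metrics reuse the pooled censoring estimate only when explicitly passed.
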