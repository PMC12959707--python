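# Methods

## The problem and the data model

Indolent B-cell lymphomas kill slowly, if at all; a large share of deaths
in modern registry cohorts are not caused by lymphoma progression but by
secondary malignancies (SM), infection (including COVID-19) and the
complications of ageing. Separating *progression-related* death (cause 1,
"CIP") from *non-lymphoma* death (cause 2, "NLM") is a competing-risks
problem: each death type precludes observing the other, so naive
Kaplan–Meier "cumulative incidence" of one cause is biased upward.

The core data model is one row per subject: follow-up `time` in years from
diagnosis (0 < time ≤ 13), a cause code (0 censored / 1 progression death /
2 non-lymphoma death), thirteen binary baseline covariates (age > 60,
male, four mutually exclusive subtype indicators, > 4 nodal sites,
bone-marrow involvement, splenomegaly, pleural effusion, LDH elevation,
hemoglobin < 12 g/dL, stage III–IV), and optional onset times for three
time-updated exposures (`sm_onset`, `ht_onset`, `covid_onset`; absent =
never exposed). All deaths from infection, COVID-19 pneumonia or other
non-lymphoma causes map to cause 2; an optional annotation column can
carry the subcause. Calendar dates appear only in the simulator's COVID
accrual rule; the core model works purely in years since diagnosis.

Time-updated exposures are expanded to counting-process rows
(start, stop] with the exposure indicator 0 before its onset and 1 at and
after it. Onset at 0 means exposed from entry; onset equal to the
follow-up time would create an empty interval and is collapsed. Person-time
is conserved exactly by construction.

## Estimators

**Kaplan–Meier / Nelson–Aalen / censoring KM.** Standard product-limit and
cumulative-hazard estimators with Greenwood / Poisson-type variances. Tie
convention throughout: deaths precede censorings at the same time, so the
censoring-distribution estimator Ĝ uses risk sets with same-time deaths
removed. Pointwise confidence bands for survival default to the log(−log)
transform, which keeps bands inside (0,1); the plain (linear) band is
available. The interval method behind published survival CIs is typically
unstated, and log(−log) is the common software default.

**Aalen–Johansen CIF.** CIF_k(t) = Σ_{t_j≤t} Ŝ(t_j−)·d_kj/n_j with Ŝ the
all-cause Kaplan–Meier. At every event time CIF₁ + CIF₂ + Ŝ = 1 to
floating-point accuracy (asserted to 1e−10 in tests). The pointwise
variance is the Aalen-type counting-process estimator (the form used by
standard survival software; the exact formula is spelled out in the
docstring) and is cross-checked in the tests against both an independent
library implementation and a subject bootstrap.

**Cause-specific Cox.** Breslow-tie partial likelihood maximized by
Newton–Raphson with step-halving (the log-likelihood never decreases);
convergence when max|score| < 1e−8 or the relative log-likelihood change
is < 1e−10, cap 50 iterations. Competing-cause failures are censored at
their failure time. Monotone likelihood (complete separation) is detected
by coefficients exceeding ±15 on the log scale; the coefficient is capped
and flagged, and the fit reports non-convergence. Risk-set sums are
accumulated by suffix cumulative sums over time-sorted rows, so one Newton
iteration costs O(n log n + E·p²). Efron tie handling is deliberately not
implemented: ties are processed jointly at a grid point (Breslow), the
simpler convention; with continuous simulated times the two coincide.

**Fine–Gray.** The subdistribution risk set keeps competing-cause failures
beyond their failure time with weight w_i(t) = Ĝ(t)/Ĝ(min(T_i, t)). The
weighted Breslow likelihood uses the same Newton driver; the weighted sums
decompose into a suffix term (natural risk set) plus Ĝ(t) times a prefix
term over competing failures, so the cost matches the Cox fit. The default
variance is the sandwich I⁻¹(Σᵢ UᵢUᵢᵀ)I⁻¹ over per-subject score
contributions; both it and the model-based inverse information ignore the
variability of the estimated censoring weights — a documented
approximation (the exact 1999-style variance with censoring-weight
correction is out of scope), cross-checked against a subject bootstrap in
the tests and in close agreement with an established reference
implementation on fixed data (coefficients to 1e−6, SEs to ~1%).

**Gray's test.** Implemented as the score test of the Fine–Gray model with
group-indicator covariates evaluated at the null (df = groups − 1). This
is not Gray's original ρ-weighted statistic, but it targets the same null
(equal subdistribution hazards) and is validated three ways: a permutation
reference for the same statistic, type-I error calibration
(rejection at nominal 0.05 measured at 0.03–0.05 over 400+ null
replicates), and exact agreement with the log-rank test when no competing
events exist (max |Δp| < 1e−14 across 100 datasets — without competing
events and ties the score test *is* the log-rank test).

**Aalen additive hazards.** λ(t|x) = β₀(t) + Σ β_k(t)x_k estimated by the
classical unweighted least-squares increments at each uncensored event
time, ties merged into one grid point, covariance increments
(XᵀX)⁻¹Xᵀdiag(dN)X(XᵀX)⁻¹. Estimation stops at the first event time whose
risk-set design is numerically singular (condition number > 1e12, recorded
as `estimable_until`) — late in follow-up risk sets shrink and covariate
columns collapse. A `cause` argument restricts dN to one cause for
cause-specific effect curves; both all-cause and cause-restricted modes
are exposed because either choice is defensible for overlay figures.
Exact reductions hold by construction and are asserted at 1e−12:
intercept-only = Nelson–Aalen; one binary covariate, untied = difference
of per-group Nelson–Aalen curves. For subject-level data (all start = 0)
the implementation uses a vectorized path (cumulative outer products +
batched solves) that is bit-identical to the generic counting-process
loop.

**Average slope.** The "constant effect per year" summary of a covariate
is the OLS slope of B_k(t_j) on t_j over the estimable grid. Its p-value
is a two-sided subject-level (cluster) bootstrap: resample subjects with
replacement, refit, and report 2·min(P*(slope ≤ 0), P*(slope ≥ 0)) with
the (1+count)/(B+1) correction. The bootstrap is the package's own choice
of inference method (none is standard for this summary). Measured null
calibration: rejection 0.042 at nominal 0.05 with 400 subjects and 250
resamples over 1000 null replicates — mildly conservative, inside the
0.03–0.07 acceptance band.

**β(t) summarization.** β_raw on interval j is (B(t_j) − B(t_{j−1}))/(t_j −
t_{j−1}), indexed at the right endpoint (the anchoring is a convention;
left or midpoint indexing shifts times by at most one grid step). LOESS is
local *linear* regression with tricube weights over the ceil(span·n)
nearest neighbours and no robustness iterations; it reproduces linear
inputs exactly and matches the classical reference implementation to
< 1e−6. The plateau threshold is max{z_{1−α/2}·MAD(β_raw − β_smooth),
ε·max|β_smooth|} with α = 0.01, ε = 0.03 and the MAD left *unscaled* (no
1.4826 consistency constant — none is prescribed). The centred 7-point
moving average for the plateau runs over the smoothed curve (more stable;
the raw curve is available via a flag), windows truncated at the grid ends
are ineligible, and a plateau must contain at least 7 full-window points.
The plateau search is verified against an exhaustive run scan on 1000
random curves, and the whole summary is scale- and time-shift-equivariant
(property-tested). An optional `max_time` truncates the grid before
summarizing: late oscillations over nearly empty risk sets are not
interpretable, and no principled numeric cutoff exists, so the argument is
exposed rather than hard-coded; the end-to-end recovery harness uses 10
years.

**Concordance.** Harrell's c for cause k counts pairs (i, j) with i
failing from cause k and either t_j > t_i or — under the default
subdistribution rule — j failing from the competing cause at any time
(such a j can never have the cause-k event, so it remains "at risk" in the
subdistribution sense). Risk ties count 1/2; two cause-k failures at the
same time are not comparable. Verified against exhaustive pair enumeration.

## Synthetic study conditions

The generator emulates the structure of a ~1,000-subject multicenter
LGBCL registry; its defaults *are* the study conditions and are not
per-test dials:

- subtype mixture 0.658 / 0.197 / 0.101 / 0.044 (FL, extranodal MZL,
  nodal MZL, MCL); covariate prevalences from the published Total column
  (age > 60: 0.298, male: 0.488, > 4 nodes: 0.259, BM: 0.324, spleen:
  0.158, pleural effusion: 0.035, LDH: 0.181, Hb < 12: 0.137, stage
  III–IV: 0.592), drawn independently — only marginals are published, and
  a correlation structure would be invented;
- cause-specific hazards λ_k(t) = λ_k0·exp(xᵀβ_k + Σ_e on_e(t)(γ_ek +
  g_ek(t − onset_e))) with multivariate-analysis effect sizes as truth:
  cause 1 (progression) age 2.32, MCL 5.93, nodal MZL 2.64, anemia 2.30;
  cause 2 (non-lymphoma) age 3.39, male 1.99, pleural effusion 5.45, LDH
  2.38, SM exposure 4.81. HT uses the univariate sizes (2.25 / 2.72; it
  never entered a published multivariate competing-risks model) and COVID
  is null on both causes (its multivariate effect was null and its
  published effect curve near-zero);
- baseline rates λ₁₀ = 0.00209, λ₂₀ = 0.00163 per year and onset clocks
  sm = 0.00585, ht = 0.0040, covid = 0.35 per year (with accrual uniform
  on calendar 2011–2023 and COVID onsets kept only inside 2020–2023),
  calibrated once, at n = 300,000, so the expected death fractions
  (~3.2% progression, ~4.2% non-lymphoma) and observed group sizes
  (~3.8% SM, ~2.6% HT, ~20.3% COVID) match the published cohort under
  uniform 1–13 y administrative censoring;
- death times by piecewise-exponential inversion over exposure-change
  segments (exact for the piecewise-constant model; competing cause drawn
  proportionally to the cause-specific rates at the drawn time). When a
  time-varying effect profile g is active the hazard is discretized to
  0.05-year steps and that discretized model is the ground truth (peak
  location shifts by at most 0.025 y).

**What the generator does not emulate** — treatment assignment and
response, center effects, covariate correlations, informative censoring,
and calendar-driven mortality waves. Passing tests therefore demonstrate
that the estimators recover the truths of this idealized registry, not
that the published clinical effect estimates are correct.

**Recovery harness for β(t).** `peaked_recovery_config` gives half the
subjects an SM exposure from entry whose log-effect on progression death
is g(u) = u·e^{−u/4} (peak exactly at 4 y, baseline rates 0.05/0.02,
no other effects), and records follow-up on a 0.1-year grid the way
registry visit data are recorded. The coarse grid matters: on a
continuous event grid the difference quotients ΔB/Δt have heavy-tailed
noise (tiny inter-event gaps produce unbounded spikes, and the mean of
1/Δt over a LOESS window does not concentrate), whereas tie-merged grid
points average several events per increment and the chain becomes stable.
With n = 3,000, LOESS span 0.35 and summarization truncated at 10 y, the
recovered t_peak falls in [3, 5] years in ~85–88% of replicates
(acceptance requires ≥ 80% over 100 replicates).

## Pipeline conventions

- The univariate screen admits covariates at raw p < 0.05 per outcome; no
  multiple-testing adjustment is applied anywhere, deliberately — the
  screen-then-fit policy is itself the analysis shape being reproduced,
  and its false-positive behaviour is tested (a null cohort screens ≈
  0.05 × 13 covariates).
- Overall survival uses a cause-specific Cox fit on all-cause death;
  the NLM and CIP outcomes use Fine–Gray fits.
- The additive stage fits baseline covariates jointly (FL is the reference
  subtype; the four subtype dummies plus intercept would be collinear) and
  each time-updated exposure in its own bivariate model on the grid
  starting at the first onset — earlier the exposure column is identically
  zero and the singularity rule would abort at the first event.
- Group assignment for the characteristics table: SM = any SM onset,
  HT = HT onset without SM, control = neither. SM takes priority when both
  occurred; the source cohort's handling of the overlap is unknown, so the
  priority rule is a documented package choice.
- 2×2 group comparisons default to the Yates-corrected chi-squared test,
  switching to Fisher's exact test when any expected cell is below 5
  (`method="auto"`); `method="chi2"` forces the corrected chi-squared
  everywhere, which is what reproduces every published pairwise p exactly.
  Fisher's exact test is only available for 2×2 tables; sparse r×2 tables
  fall back to chi-squared with a method note.
- Percentages are rounded half-up to one decimal, matching publication
  style.
- The COVID-era landmark analysis is a generic landmark filter (drop
  subjects with follow-up ≤ the landmark, rebase the clock) at a
  configurable time, since anchoring to a calendar date requires an
  accrual column that the core model deliberately omits.
- `run_analysis` is deterministic given the seed; the manifest records the
  config hash, seed and version, and rerunning with the same inputs
  reproduces every CSV byte-for-byte.

## Problem sizes

The test-suite and acceptance-script simulation sizes are chosen to make
Monte-Carlo noise small relative to each tolerance while keeping a few
minutes' total runtime: n = 50,000 for the closed-form CIF comparison
(binomial SE ≈ 0.002 against a 0.01 sup-norm bound), n = 2,000–4,000 for
hazard-ratio recovery (3·SE bands), 200 replicates for coverage,
100 replicates for the end-to-end peak recovery, and 400–1,000 replicates
for test calibration (a 200-replicate rejection estimate has SE ≈ 0.015,
too coarse for a 0.03–0.07 band, so calibration uses 1,000).

## Known limitations

- No left truncation or interval censoring; entry is diagnosis.
- Fine–Gray standard errors omit the censoring-weight estimation term.
- Gray's test is the score-test variant; p-values differ somewhat from the
  ρ-weighted original in small samples.
- No confidence bands on β(t): differentiating and smoothing B(t) does not
  propagate its pointwise variance in closed form, and no band definition
  is prescribed; B(t) itself carries variances.
- The additive model offers no overall significance test beyond the slope
  summary, and no semiparametric (constant-coefficient) variant.
- The c-index has no censoring-weight (IPCW/Uno) correction; with heavy
  censoring Harrell's c is optimistic.
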