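# lymphrisk

Competing-risks mortality analysis for low-grade B-cell lymphoma (LGBCL)
cohorts — follicular, marginal-zone and mantle-cell lymphoma registries in
which long survival makes *non-lymphoma* mortality (secondary malignancy,
infection, COVID-19) as important as progression-related death, and in
which a single all-cause survival model obscures which factor drives which
kind of death.

The package is written for biostatisticians and clinical researchers who
need the full analysis chain from a subject-level table to cause-separated
risk estimates:

- **Nonparametric estimation** — Kaplan–Meier survival, Nelson–Aalen
  cumulative hazard, the censoring-distribution Kaplan–Meier Ĝ, and the
  Aalen–Johansen cumulative incidence function CIF_k(t) = Σ_{t_j≤t}
  Ŝ(t_j−) d_kj/n_j for each competing cause.
- **Regression** — cause-specific Cox models (Breslow ties, Newton–Raphson
  on the partial likelihood) and Fine–Gray subdistribution-hazards models
  in which competing-cause failures remain in the risk set with
  inverse-probability-of-censoring weights w_i(t) = Ĝ(t)/Ĝ(min(T_i, t));
  Gray's test as the Fine–Gray score test at the null.
- **Aalen additive hazards** — λ(t|x) = β₀(t) + Σ_k β_k(t) x_k, fitted by
  least-squares increments ΔB(t_j) = (X_jᵀX_j)⁻¹X_jᵀ dN(t_j) on the
  event-time grid, with time-updated exposure states (secondary malignancy,
  histologic transformation, COVID-19) entering as counting-process rows.
- **β(t) curve summarization** — the instantaneous absolute risk difference
  β(t) = ΔB/Δt, LOESS-smoothed (span 0.35), summarized by t_peak,
  t_zero-cross and a plateau interval: the longest post-peak run where the
  centred 7-point moving average of |β(t)| stays below
  max{z_{1−α/2}·MAD(β_raw − β_smooth), ε·max|β(t)|} with α = 0.01, ε = 0.03.
- **Discrimination** — Harrell's concordance index with a competing-risks
  comparability rule.
- **Synthetic cohorts** — a generator reproducing the study structure
  (subtype mixture, covariate prevalences, two log-linear cause-specific
  hazards, exponential exposure onsets with a COVID calendar window,
  uniform 1–13 y administrative censoring) so every stage is testable
  without access to registry data.

## Worked example

`examples/05_beta_curves.py` recovers a known time-varying exposure effect
end to end (counting-process expansion → cause-restricted Aalen fit →
ΔB/Δt → LOESS → summary):

```
true effect peak:        4.00 y
recovered t_peak:        3.90 y
zero-cross:              none
plateau:                 [7.40, 9.60] y
adaptive threshold:      0.1045 (absolute risk difference / y)
```

Half the simulated subjects carry a secondary-malignancy exposure whose
log-effect on progression death peaks at exactly 4.0 years; the chain
recovers the peak within one grid step, finds no downward zero-crossing
(the effect stays positive), and flags the late near-zero stretch as the
plateau. `examples/02_cumulative_incidence.py` shows the estimator against
the constant-hazard closed form CIF₁(t) = λ₁/(λ₁+λ₂)·(1−e^{−(λ₁+λ₂)t}):

```
horizon   OS(KM)   CIF progression (est | exact)   CIF non-lymphoma (est | exact)
   2 y    0.774    0.138 | 0.141                  0.088 | 0.088
   4 y    0.587    0.250 | 0.250                  0.163 | 0.156
   8 y    0.354    0.396 | 0.398                  0.251 | 0.249
```

The other examples cover cohort simulation and Table-1-style description
(`01`), the univariate screen → multivariate Fine–Gray models per outcome
(`03`), additive-hazards slopes (`04`), the concordance index (`06`) and
the full report-bundle pipeline (`07`). A thin CLI wraps the pipeline:

```bash
lymphrisk simulate --n 1047 --seed 7 --out cohort.csv
lymphrisk validate cohort.csv
lymphrisk analyze --input cohort.csv --out results/ --seed 7
lymphrisk summarize-curves cohort.csv -c age_gt60
```

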