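# Methods

## The model family

`lungdr` fits 2-year overall survival (OS) of locally advanced NSCLC
cohorts as a function of the radiotherapy schedule. The outcome unit is a
published cohort: `N` patients, an observed OS percentage (converted once
at load time to an integer survivor count `x = round(OS/100 × N)`, half-up,
so the likelihood is a proper binomial), a treatment type (RT alone,
sequential chemo-RT, concurrent chemo-RT), a schedule `(D, d, T)` and a
stage mix `f_i` over stages I/II/IIIA/IIIB.

Tumour dose is expressed as equivalent dose in 2 Gy fractions corrected
for accelerated repopulation and, under concurrent chemo-RT, for
radiosensitisation:

    EQD2_tum = RS · D · (α/β + d)/(α/β + 2) − λ · max(T − T_k, 0)

Per-stage survival is a probit in EQD2 attenuated by three multiplicative
factors:

    OS_i = Φ[(EQD2_tum − EQD2_tum50(S_i)) / (m · EQD2_tum50(S_i))]
           × OS_max × (1 − SLT(S_i)) × (1 − R·Y)

where `SLT(S_i) = F_SLT-i · Φ[(EQD2_NT − EQD2_NT50)/(m_NT · EQD2_NT50)]`
is survival-limiting toxicity evaluated in normal-tissue EQD2 (generic
α/β = 3 Gy, no repopulation, no RS), `OS_max` is a survival ceiling (fixed
at 85% for RT alone, reflecting distant failure without chemotherapy, and
fitted on [85, 100]% for chemo-RT), and `Y = max(2016 − publication year, 0)`
captures secular improvement at rate `R` per year. Cohort survival is the
stage-fraction-weighted mixture `Σ f_i OS_i`.

The nested family: **model 1** is the bare probit (no chemo factors, 8
parameters); **model 2** adds RS, OS_max, SLT and R (13); **model 3**
splits λ and T_k into cCRT vs RT/sCRT (15); **model 4** splits tumour α/β
by stage — I & II pooled, IIIA, IIIB (17); **model 5** lets the SLT weight
F_SLT vary by stage (21). Registered variants regroup α/β or repopulation
by treatment, histology, or by the cohort's IIIB/IIIA balance
(More-IIIA vs More-IIIB cohorts; the occasional exactly balanced cohort is
grouped with More-IIIA). Histology groupings mix over histology fractions
exactly as stages mix over stage fractions, and require histology columns
in every cohort. For the variants that regroup repopulation or α/β by
stage the three α/β stage groups (I & II, IIIA, IIIB) are reused, since
stage I/II patients are too few in this setting to support separate
values.

## Likelihood and fitting

The objective is the Bernoulli-form binomial deviance
`−2 Σ [x ln p̂ + (N−x) ln(1−p̂)]` with predictions clipped to
`[1e−9, 1 − 1e−9]` (probit tails underflow for extreme schedules during
optimisation; negative EQD2 from heavy protraction is deliberately passed
through to the probit rather than floored — the link stays defined and the
surface stays smooth). The binomial coefficient is omitted: it shifts the
deviance by a data-only constant and dropping it keeps −2logL magnitudes
comparable across the model family.

Parameters live in boxes chosen to cover the plausible radiobiological
range: λ ∈ [0, 3] Gy/day, T_k ∈ [16, 47] days, α/β ∈ (−1.9, 100] Gy
(a profile that is still flat at 100 is reported as unbounded above),
m, m_NT ∈ (0.05, 1], EQD2_tum50 ∈ [20, 120] Gy, RS ∈ [0.8, 1.4],
OS_max ∈ [85, 100]%, EQD2_NT50 ∈ [20, 150] Gy, R ∈ [0, 0.05]/yr,
F_SLT ∈ [0, 1]. Box scalars are mapped to the real line by a scaled
logit; the stage-ordered blocks (EQD2_tum50 and F_SLT must be
non-decreasing I → II → IIIA → IIIB) are encoded as a base value plus
log-increments, making the ordering exact rather than penalised.

Optimisation is multi-start (default 20 starts: the neutral init α/β = 10,
λ = 0.6, T_k = 21, m = 0.3, EQD2_tum50 = 70 …, plus seeded Latin-hypercube
draws over the boxes), each start a Nelder–Mead simplex followed by an
L-BFGS-B polish in the unconstrained space, best optimum wins.  Fits are
deterministic given the seed.  Estimates within 0.1% of a box width of an
edge are flagged as boundary estimates.

Profile-likelihood CIs refit all remaining parameters while stepping the
parameter of interest outward from the MLE (step-doubling, then bisection
until the profiled −2logL increase is within 0.01 of χ²(1, 0.95) = 3.84);
endpoints that hit the box are flagged truncated. In overdispersion mode
the threshold is inflated to 3.84·φ. The asymptotic correlation matrix is
the inverse of a central-finite-difference Hessian of the negative
log-likelihood at the MLE in natural parameter space, normalised to unit
diagonal; a singular Hessian raises an error that names the flat
directions (common when a stage carries almost no patients).

Overdispersion is quantified by the Pearson factor
`φ = Σ (x − Np̂)² / (Np̂(1−p̂)) / (n_cohorts − k)`; `QAIC = −2logL/φ + 2k`.
When model comparison uses QAIC, φ is taken from the richest model under
comparison.

Cross-validation partitions cohorts into 10 seeded folds, refits on the
remainder and scores held-out cohorts by the patient-weighted MSE on the
percent scale, averaged over folds. This score definition is this
package's own; published cross-validation scores for this analysis are on
an unstated scale and are **not** expected to match numerically — only
the model ordering is meaningful.

## Bootstrap and escalation contrasts

The bootstrap resamples whole cohorts with replacement (the cohort, not
the patient, is the exchangeable unit in a meta-analysis), refits, and
evaluates the 60 Gy/30 fx/40 d → 74 Gy/37 fx/51 d escalation contrast per
treatment and stage at Y = 0 (durations follow the 5-fraction-per-week
calendar `T = 7·((n−1) div 5) + ((n−1) mod 5) + 1`). Failed refits are
excluded from summaries and counted rather than redrawn, keeping the
replicate count interpretable. The summary fraction "cCRT lower than
sCRT" compares the IIIA/IIIB-average contrast per replicate; the λ
comparison is available whenever the spec groups repopulation by
treatment. Both bootstrap refits and cross-validation folds default to 5
optimisation starts (data perturbations are mild, so fewer starts suffice
per refit; the count is configurable).

## Synthetic data

The generator emulates the compiled 51-cohort study design: 10 RT / 26
sCRT / 15 cCRT cohorts; doses uniform on 55–95 Gy at 1.3–3.0 Gy per
fraction; fraction numbers `round(D/d)`; durations from the weekday
calendar plus 0–7 protraction days, clipped to 16–60 days; publication
years uniform on 2000–2016; 20–400 patients per cohort (a multiplier
scales this for recovery studies); stage mixes from per-treatment
Dirichlet distributions (concentration 30) centred on the observed
per-treatment stage tables, so IIIA/IIIB dominate; optional histology
mixes centred on 43/30/27% squamous/adeno/other. Outcomes are binomial
draws from the ground-truth model's predictions, or beta-binomial with
correlation ρ when overdispersion is requested. Schedule sampling and
outcome sampling use separate seeded streams so the same design can be
re-dressed with new outcomes.

What the generator does **not** emulate: publication bias, stage
migration over calendar time, correlated design variables (real trials
choose dose and duration jointly), or centre-level covariates beyond the
beta-binomial noise. Passing recovery tests therefore demonstrate the
estimator is consistent and unbiased under the model's own assumptions,
not that the model is correct for real compilations.

## Problem sizes and numerical choices

Parameter-recovery experiments use 10 replicates (seeds 1–10) of the
default design with patient numbers ×10 and 12 optimisation starts per
fit — enough replicates for the Monte-Carlo error of the mean to sit well
inside the stated recovery tolerances (±0.25 Gy/day for λ(cCRT),
±0.08 Gy/day for λ(RT/sCRT), ±0.6 Gy for the shared α/β), at roughly
twenty seconds per full-model fit. The Table-style reference parameter
sets used as ground truth are rounded published estimates, which is why
escalation-contrast *magnitudes* computed from them are not sharp
reproduction targets — the contrast is sensitive to rounding — while
their signs and the IIIB-worse-than-IIIA ordering are robust and are
asserted in tests.

Known limitations: stage I/II parameters are weakly identified under the
study design (few such patients), so their profile intervals are wide and
the Hessian can be numerically singular along those directions; α/β
estimates interact with RS and T_k near box edges; and the escalation
bootstrap inherits whatever multimodality the refits encounter — the
per-replicate seeded multi-start mitigates but cannot eliminate local
optima.
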