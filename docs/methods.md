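# Methods

This note documents the statistical machinery, the synthetic-data model
behind the test bench, and the design decisions that were genuinely open.

## 1. Cohort model and time conventions

A cohort couples one covariate row per patient with an in-hospital event
timeline on an integer minute clock starting at hospital arrival. An event
"at minute t" occupies the half-open interval [t, t+1); the horizon is
fixed at 120 minutes, at which point patients still in arrest are
administratively censored. Exactly one terminal event per patient: ROSC,
death (termination of resuscitation), start of ECPR, or censoring at 120.
Pre-hospital adrenaline doses are top-coded at 5 ("≥ 5" as one level).

**Eligibility.** Exclusions are applied in a fixed documented order (each
patient counted once, at the first failing criterion): no resuscitation
attempt; age < 18; external cause; no arrest at EMS contact; sustained ROSC
before/on arrival; hospital without a registered ECPR case; missing final
disposition; zero time to final disposition. The ECPR-capability criterion
treats the *input cohort* as the registry: a hospital is capable if any
record in the input has an ECPR disposition there. Re-filtering a subset is
exact under the original capability context
(`apply_exclusion_criteria(..., capable_hospitals=...)`); deriving
capability from an already-filtered subset can, in a corner case (a
hospital whose only ECPR case was itself ineligible), drop further
patients — this mirrors the database-level definition of capability rather
than a per-cohort one.

**Hospital ECPR volume.** Hospitals are split at the empirical tertiles of
their ECPR case counts, rank-based: the `floor(n/3)` smallest counts bound
"low", the `floor(2n/3)` smallest bound "middle", the rest are "high"; ties
at a boundary fall to the lower category. Degenerate cases: a single
hospital is "high"; all-equal counts are all "low".

## 2. Time-dependent propensity model

The propensity of starting ECPR at minute *t* is modelled on the
subdistribution-hazard scale (Fine–Gray), with ROSC/termination before ECPR
as the competing event and administrative censoring at 120 min, fitted
separately per rhythm stratum (a mixed-stratum table is refused).

**Person-minute table.** One row per patient-minute. Treated patients
contribute rows t = 0..(ECPR minute), with the event coded on the last row.
Competing-event patients remain in the subdistribution risk sets through
minute 119 with weight 1 — within this window the only censoring is
administrative at a fixed time, so the Fine–Gray inverse-censoring weights
are degenerate at 1 — and their time-dependent covariates are frozen at the
last pre-event values (no interventions occur after ROSC/termination by
construction; the convention keeps risk sets well-defined). Censored
patients contribute rows t = 0..119, the censoring code on the last row.

**Covariates.** Time-independent: sex, age, witnessed status, bystander
CPR, initial rhythm, bystander AED, physician-staffed unit, paramedic
shock, advanced-airway type, pre-hospital adrenaline count, pre-hospital
ROSC, call-to-hospital time, and hospital ECPR-volume category.
Time-dependent: in-hospital defibrillation, intubation and adrenaline
indicators, each switching on the minute *after* the intervention, so that
an intervention during minute t cannot predict treatment at minute t.
Categoricals are reference-coded against the first level in the documented
dictionary order; indicator columns that never vary within a stratum (e.g.
initial rhythm in the shockable cohort) are structurally uninformative and
omitted. The adrenaline dose count enters as a single numeric column.

**Fitting.** Breslow handling of tied event minutes (minute resolution
produces heavy ties; Breslow keeps the likelihood simple and
oracle-checkable). Newton iteration with step-halving on internally
standardised covariates (location shifts cancel in the risk-set ratios;
scales are folded back into the returned coefficients); convergence at
max-abs gradient < 1e-8, at most 100 iterations. Diagnostics raised as
errors: zero-variance covariate ("degenerate covariate"), a coefficient
diverging past |β| > 10 with a non-vanishing gradient ("separation"),
non-convergence with the iteration count.

**Score scale.** Matching distances live on the linear predictor
(log-hazard) scale, not a transformed probability; the caliper SD is the SD
of the linear predictor over treated patients evaluated at their treatment
minutes. Which population's SD defines the caliper is a genuinely open
choice; treated-at-treatment-time is used because that is the population
actually being matched.

## 3. Sequential risk-set matching

At each minute with at least one ECPR initiation, the candidates are
patients still undergoing resuscitation during that minute whose own ECPR
(if any) starts strictly later — a terminal event *during* minute t removes
candidacy at t, the strict reading of "not before or within the same
minute" applied symmetrically to all terminal events. Matching is greedy
1:1 nearest-neighbour by absolute score difference within a caliper of 0.2
score SDs, with replacement; minutes are processed in increasing order,
treated patients within a minute in a seeded random order, and distance
ties break towards the smaller control id (the ordering and tie rule are
unspecified in the design being emulated; both choices are deterministic).
Treated patients with no in-caliper candidate are recorded unmatched and
excluded from analysis. The "% controls later treated" summary counts
unique patients ever used as a control.

## 4. Balance and effect estimation

Standardised mean differences: continuous
`(m1 − m2)/sqrt((s1² + s2²)/2)` with sample variances; binary the same
with `p(1 − p)` variances; multi-level categoricals collapse to the single
non-negative Mahalanobis-type SMD over level proportions (one printed
number per variable; the exact multi-level convention is not standardised,
so the multivariate form is a documented choice). |SMD| ≥ 0.25 raises the
imbalance flag. In matched balance tables each arm has one row per pair, so
reused controls count once per pair, consistent with replacement.

For 1:1 pairs with one binary exposure the conditional ML odds ratio is
`n10/n01` (concordant pairs are ancillary), with a Wald 95% CI
`exp(log OR ± 1.96·sqrt(1/n10 + 1/n01))`; the CI construction is a design
choice (the emulated analysis states none), and the point estimate is
cross-checked in the tests against a numeric maximiser of the full
conditional likelihood. A zero discordant count yields a flagged
"zero/infinite OR" with a one-sided 95% profile bound from the conditional
binomial likelihood instead of a Wald interval. Pairs sharing a control are
treated as independent in the likelihood; the robustness limitation of
reused controls is documented here rather than corrected, mirroring the
emulated analysis.

## 5. Synthetic registry generator

The generator emulates the statistical structure the analysis assumes —
not resuscitation physiology.

**Covariates** are drawn from marginals resembling a national OHCA registry
population arriving in arrest (80% male; age ≈ N(62, 15) truncated to
18–100; 72% witnessed; 52% bystander CPR; call-to-hospital ≈ log-normal
with median ~32 min; 12 hospitals with geometrically skewed volume). The
default configuration is a shockable-rhythm cohort; rhythm probabilities
are configurable for mixed cohorts.

**Events.** Minutes 0..119 are simulated forward. Each minute, intervention
onsets (defibrillation while the rhythm course is shockable, intubation,
adrenaline with a higher re-dose hazard) are drawn first, then one terminal
event among {ECPR, ROSC, death} from a categorical draw whose cell
probabilities are inverse-logit linear in covariates, elapsed time, current
intervention indicators and (optionally) a latent refractoriness variable;
no event means the patient stays in arrest; survivors are censored at 120.
The ECPR hazard is zero before minute 6 and decays after minute 35
(escalation is decided early; the window also keeps control crossover
modest, ~10–15% of unique controls). Per-minute hazards are validated to
sum to ≤ 1.

**Outcomes.** Both potential 30-day survival outcomes are drawn from one
shared uniform per patient against logistic probabilities
`p_a = logit⁻¹(α + γ·X + a·β_treat)`; the realised outcome follows the
realised treatment. This makes `β_treat = 0` give identical potential
outcomes patient-wise, and raising `β_treat` monotone — and it makes
`β_treat` an exactly defined conditional estimand for the bench. The
realism cost is deliberate: survival is *not* mediated by the ED
disposition (a terminated patient can "survive"), so passing tests say
nothing about disposition-mediated outcome pathways in real data.
Favourable neurological outcome (CPC 1–2) is drawn only among survivors.
An optional linear decay of the benefit with treatment minute is available
but off by default (no established model for it).

**Confounding structure.** In the default configuration treatment timing
depends on *observed* prognostic covariates (younger and witnessed patients
are escalated more), creating treatment-timing confounding that the
propensity model can in principle remove. The `bias_scenario` preset adds
an unobserved standard-normal latent variable that lowers the ROSC hazard,
raises the ECPR hazard and lowers survival, with `β_treat = 0`: the
canonical resuscitation-time-bias null. The `unconfounded_config` preset
makes the treatment hazard a pure intercept (calibrated to keep the treated
fraction near the default's ~11%) for clean null and coverage checks.

**Missingness.** MCAR masks each covariate cell independently; MAR
modulates the rate by always-observed drivers (age, witnessed), rescaled to
preserve the marginal rate. Event times, dispositions and outcomes are
never masked. A small configurable fraction of deliberately ineligible
records (default ~5% total) exercises the study-flow filter.

## 6. Imputation

Iterative random-forest imputation in the missForest style: initialise with
observed mean/mode; loop over incomplete variables in increasing
missingness order; fit a random-forest regressor (continuous) or classifier
(categorical) on the observed rows and predict the missing rows; stop when
the normalised change statistic first increases — tracked separately for
continuous (`Σ(new−old)²/Σnew²` over imputed cells) and categorical
(fraction of changed imputed cells) variables, stopping when every present
type increases — and return the previous iterate, or stop at `max_iter`.
Defaults: 100 trees, unlimited depth, deterministic per-variable seeds
derived from the call seed. Single imputation only; observed cells are
never modified; categorical imputations can only take observed levels.
Imputation is intended to run after the eligibility filter.

## 7. Estimator bench

Each replicate runs simulate → filter → fit → match → estimate and records
the matched conditional log-OR (with CI) and the naive ever-vs-never 2×2
log-OR (Wald CI; zero cells get a flagged 0.5 correction). The recovery
target is the configured *conditional* log-OR; marginal/conditional
non-collapsibility is kept small by the modest covariate effects in the
outcome model and is not adjusted away. Replicate failures (separation, no
pairs, no discordant pairs) are counted and excluded from aggregates,
mirroring the dropping of unmatched treated. Per-replicate seeds derive
from the base seed via `SeedSequence(base, spawn_key=(rep,))`.

Problem sizes used by the acceptance checks: 200 replicates of n = 2000
per scenario (recovery at ln 2, unconfounded null for coverage, latent
confounding for the bias ordering); the bundled examples use smaller
benches (30 × 1000) for quick inspection.

## 8. Known limitations

* The generator's data-generating hazards are cause-specific, while the
  propensity model is a subdistribution (Fine–Gray) fit with frozen
  covariates for competing-event patients — deliberately the emulated
  method. One visible consequence: the fitted time-dependent intervention
  coefficients absorb "still actually at risk" information and come out
  larger than the generating values, so matching on the combined score can
  trade baseline prognosis against in-hospital interventions. This leaves
  a small residual bias under observed-covariate confounding (~+0.05 on
  the log-OR scale in the default configuration), visible in the bench.
* Reused controls make pairs dependent; the conditional likelihood treats
  them as independent (documented, not corrected).
* The synthetic registry has no disposition-mediated outcomes, no
  inter-hospital quality differences beyond volume, and no pre-hospital
  ECPR; conclusions from the bench are about estimator behaviour under the
  stated data-generating process, not about clinical effectiveness.
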