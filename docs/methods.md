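# Methods

## Model

`cvdms` implements a discrete-time Markov illness–death model on a quarterly
age grid. The state space is {CVD-free, CVD, dead}; CVD entry is
irreversible (no recovery edge) and death is the only absorbing state, so
mortality is all-cause — the model does not distinguish CVD deaths from
other deaths. Age is measured in months on the grid 480, 483, …, 1200
(40–100 years, 241 points, 240 intervals of 0.25 years). A state is assigned
at each grid point; a transition "happens" in the interval between points.

Per-step transition probabilities follow, for each transient origin *i*,
a multinomial logit over the allowed destinations:

    log(p_ij / p_i,stay) = a_ij + b1_ij·x + b2_ij·x² + δ_ijᵀ·Period,
    x = (age_months − 840) / 120

The reference destination is the stay state (FREE→FREE, CVD→CVD). With
origin CVD the model degenerates to a binary logit (stay vs die). Predicted
probabilities are invariant to the reference choice and to the age
centering/scaling constants (both checked numerically in tests); centering
at 840 months (age 70) with scale 120 (one decade) keeps the design
well-conditioned. The period variable is dummy-coded with the first
five-year period as reference; "predicting for period k" means activating
period k's dummy and zeroing the rest.

Models are fitted separately per origin state. The multinomial likelihood of
the panel factorizes over origins, so the per-origin maximum-likelihood
estimates coincide with a joint fit; separate fits are simpler and expose
per-origin convergence diagnostics. Period effects are origin- and
destination-specific throughout.

### Estimation

Person-period rows are aggregated to covariate cells (age × period, within
stratum) with multinomial outcome counts before fitting: the covariates are
all discrete, so a register-scale panel of tens of millions of rows
collapses to at most 1,200 cells per origin without any change to the
likelihood. The solver is a damped Newton–Raphson on the exact weighted
multinomial log-likelihood with analytic gradient and Hessian (step halving
whenever a full step would decrease the log-likelihood). Standard errors
come from the observed information matrix at the optimum. The solver is
cross-checked against an independent row-level multinomial-logit
implementation in the test suite and agrees to ~1e−15.

Convergence requires a parameter step below 1e−9 and a gradient below
1e−6·N. No regularization is applied; a coefficient passing |β| > 30 during
iteration aborts with a separation error naming the offending covariate
(at quarterly probabilities, |β| = 30 corresponds to probabilities below
1e−13 — far outside any data-supported value).

### Stratification

Three schemes: `total` (one model), `by_gender` (two), and
`by_gender_education` (six). Stratifying variables never enter as
covariates: the gender models do not control for education and vice versa,
so each stratum's trends are estimated as they exist in that subpopulation.
Empty strata raise rather than silently vanish.

## Markov functionals

All metrics are period (synthetic-cohort) quantities: a cohort is pushed
through one period's age-specific matrices as if it lived its whole life
under that regime. Conventions, each pinned by a dedicated test:

* **Occupancy counting** — occupancy is evaluated at interval starts; each
  occupied start contributes 0.25 years. A deathless chain therefore yields
  exactly 60.0 expected years from age 40.
* **Horizon truncation** — the recursion stops at 1,200 months and survivors
  contribute nothing beyond it. This biases expectancies downward at extreme
  ages; at realistic mortality levels the survivor mass at 100 is small.
* **Onset age** — a first FREE→CVD transition in the interval [a, a+3) is
  assigned onset age a+3 (the destination grid point, where the event is
  first observed). Onset certain in the first interval gives 40.25 years.
* **Lifetime risk** — the total mass of the first-passage distribution,
  Σ_t P(still FREE at t)·p(FREE→CVD at t); because entry is irreversible,
  "occupying FREE" and "never having left FREE" coincide.
* **Conditional TLE at 65** — expected remaining years alive from 780
  months, starting in the CVD state, under the same counting conventions.
* **Cohort definition** — lifetime risk, onset age and the age-40
  expectancies condition on being CVD-free at exactly 480 months; prevalent
  cases at 40 are excluded.
* **Degenerate inputs** — conditional quantities with an empty conditioning
  event (mean onset age under zero lifetime risk, gain share under zero TLE
  change) return NaN with a `RuntimeWarning` instead of raising, so batch
  tables never abort.

Constant-probability chains admit truncated-geometric closed forms (e.g.
lifetime risk = p_c(1−(1−p_c−p_d)^240)/(p_c+p_d)); the implementation matches
these to 1e−10. Every functional is also validated against a
microsimulation oracle that samples individual trajectories directly from
the transition matrices and recomputes each metric empirically with the same
conventions; matrix and microsimulation values agree within three
Monte-Carlo standard errors at 200,000 trajectories.

## Synthetic register generator

Real inputs of this kind are linked administrative registers that cannot be
redistributed, so the package ships a generator whose output has the same
schema and structure: quarterly person-period rows with period, gender and
education labels, irreversible CVD entry, age-increasing incidence and
mortality, excess mortality in the CVD state, and period trends. The
generating model has exactly the estimation model's functional form (plus
optional additive intercept shifts by gender and education), which makes
coefficient-level recovery checks possible.

Scenario defaults (quarterly-logit coefficients on the centered/scaled age
scale) were chosen once to produce register-plausible magnitudes for a
high-income European population — first-period lifetime risk ≈ 0.72, total
life expectancy at 40 ≈ 38 years rising to ≈ 41, onset age ≈ 69.5 rising to
≈ 72, mortality falling faster than incidence across periods:

| scenario | description |
| --- | --- |
| `baseline` | age-increasing incidence/mortality, CVD excess mortality, later periods healthier; homogeneous across gender and education |
| `no_cvd` | incidence switched off (survival-only chain; degenerate checks) |
| `constant_hazard` | age- and period-constant probabilities (geometric closed forms) |
| `strong_gradient` | baseline plus protective education (±0.3–0.35 on the logit) and adverse male (+0.22–0.30) intercept shifts, with entry education distributions drifting upward across periods |

Entry distributions default to uniform periods, a 50/50 gender split and a
40/35/25 basic/secondary/tertiary education mix; `strong_gradient` replaces
the latter with a period-specific drift (basic falling 49%→27%, tertiary
rising 22%→35%, roughly tracking observed attainment change in Finland).
Everyone starts CVD-free at 480 months (a configurable probability can start
people in the CVD state, used for conditional-survival checks); an optional
left-truncation switch drops rows before a configured observation age to
mimic register entry mid-life.

Randomness is consumed in a fixed, documented order — one block of four
attribute uniforms per person, then trajectory uniforms drawn as row-major
(person, step) matrices in person chunks (person-major, age-minor) — so a
seed fully determines the output byte-for-byte. `simulate_transition_counts`
consumes the identical stream but returns aggregated covariate-cell counts
without materializing rows; its equality with aggregating the row-level
table is asserted in tests and it is used for large replication studies.

**What the generator does not emulate** — and hence what passing tests do
not establish about real registers: no emigration or loss to follow-up
(trajectories end only in death or the horizon), no hospital-episode or
diagnosis-code process (states are directly observed, so there is no
misclassification), no diagnosis-history lookback problem (synthetic
histories are complete from age 40), no household or caregiver structure,
no true calendar-cohort bookkeeping beyond the period label, and exact
functional-form agreement between generator and estimator (real-world
misspecification of the age/period shape is not represented). Tests
establish internal correctness of estimation and life-table arithmetic, not
robustness to these features.

## Education standardization

Counterfactual trends fix the education composition: the standardized
transition matrix for a period is the entrywise convex combination of the
education-specific matrices, weighted by the person-period education shares
pooled over the full observation window (computed within gender, since
standardization is applied within gender contexts). Mixing happens on the
probabilities, not on the final metrics; a mixture of row-stochastic
matrices is row-stochastic, so all downstream functionals apply unchanged.
Weights are age-marginal (one triple per gender); `EducationWeights` accepts
any fixed distribution, so age-specific or externally chosen weights can be
supplied if desired. On data with upward education drift and protective
education gradients, the standardized first-to-last-period gain in CVD-free
expectancy is bounded above by the unadjusted gain (checked as an
acceptance property).

## Reporting

Metric tables hold one row per (period, subgroup) with unrounded values;
display rounding follows the conventional precision (years to one decimal,
percentages to whole points). Disparity gaps are computed on the metric's
native scale and rounded the same way; gaps computed from the packaged
Finland 1996–2020 reference table use the printed (rounded) cells, while
pipeline outputs use unrounded values — the two can differ in the last
digit. The TLE-gain decomposition reports Δtle, Δe_free, Δe_cvd between two
periods and the CVD-free share of the gain rounded to the nearest percent.

## Validation problem sizes

The shipped validation suite uses: 200,000 microsimulated trajectories per
scenario for the matrix-vs-simulation agreement; one 500,000-person cohort
for coefficient recovery within three estimated standard errors; fifty
100,000-person replicates for the bias check, with each coefficient's mean
bias bounded by Bonferroni-corrected Monte-Carlo error (family-wise
three-sigma across the 21 coefficients — a per-coefficient three-sigma rule
on 21 simultaneous estimates would flag pure noise ~5% of the time); and a
150,000-person register for the standardization contrast. These sizes give
standard errors one to two orders of magnitude below the effects being
checked.

## Limitations

* The Markov assumption: transition probabilities depend only on the current
  state, age, period and stratum — not on disease duration or history.
  Appropriate for population-level means and probabilities; not for
  individual trajectory prediction.
* Period perspective: metrics describe a synthetic cohort under one period's
  regime, not any real birth cohort.
* Single absorbing state: cause-specific (CVD-only) mortality is out of
  scope by construction.
* No variance or confidence intervals for the derived metrics (only the
  coefficient-level standard errors); horizon truncation at age 100 biases
  expectancies downward at extreme ages.
* The generator's parametric truth shares the estimator's functional form;
  recovery results do not speak to misspecification bias.
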