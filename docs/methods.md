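# Methods

## Model

The package projects one country's economy year by year over a fixed
horizon (default 2020–2050 inclusive, 31 model years) under two scenarios
and measures the disease burden as the discounted cumulative GDP gap
between them.

**Production.** Output is Cobb–Douglas, `Y = A·K^α·H^(1−α)`. The status-quo
GDP path is an *input* (a projection from national accounts); the engine
backs total factor productivity out of it, `A_t = Y_t/(K_t^α H_t^(1−α))`,
so the status-quo run reproduces the projection to machine precision. The
counterfactual holds that calibrated `A_t` fixed: technology is exogenous
and unaffected by disease. Output and capital are in millions of
purchasing-power-adjusted international dollars (2017 INT$).

**Demography.** Populations are single-year-of-age grids (ages 0–100) with
a closed terminal group that absorbs survivors of the top two ages.
Cohorts evolve by `n_t^(a) = (1−σ_{t−1}^{(a−1)}) n_{t−1}^{(a−1)}` with a
constant birth inflow at age 0, identical in both scenarios. The
counterfactual removes cause-specific mortality using the multiplicative
split `(1−σ) = (1−σ_r)(1−σ_{−r})`. For single-lineage cells the
counterfactual population equals the status-quo count divided by the
accumulated cause-specific survival `Π(1−σ_r)`, and this identity is what
the implementation exploits; because the closed terminal group pools two
lineages, the terminal row is instead evolved by the absorbing recursion
under the split mortality, which makes the product-form result identical
(to 1e−9 relative and better) to an independent forward re-projection —
both routes are kept and cross-checked in the tests.

**Morbidity.** The labor-force participation rate in the counterfactual is
raised by `ℓ̄ = ℓ / Π_τ (1 − p^τ σ_r ξ)` along cohort lineages, where
`ξ = YLD/YLL` converts the cause-specific mortality rate into an
equivalent participation loss from survivors' disability. Cells with
disability but no deaths (`YLL = 0 < YLD`) would make `ξ` infinite; they
are capped at a configurable `xi_cap` (default 10, the upper end of
plausible YLD/YLL ratios for this disease). The survivor weight `p` is a
scalar in [0, 1] (default 1.0: morbidity fully persists in survivors of
averted deaths); this is an interpretation of an under-determined term and
is exposed for sensitivity analysis rather than asserted as fact.

**Informal care.** Each prevalent patient costs `hours/workweek` units of
labor (default 4.0 h/week against a 35.9 h full-time week, i.e. 0.11
units; sensitivity range 0.285–8.3 h/week). The total is distributed over
caregiver ages; absent an observed caregiver age distribution, the default
weights are proportional to status-quo effective labor by age and can be
overridden per input panel. In the counterfactual the deduction scales
with the surviving prevalence, `(1−ρ)`.

**Capital.** `K_{t+1} = (1−δ)K_t + s_t Y_t`, initialized at an input
`K₀`. In the counterfactual a fraction `χ` of the averted treatment cost
is added to investment, `K̄_{t+1} = (1−δ)K̄_t + s_t Ȳ_t + ρχ·TC_t`, and the
year loop is coupled: each year's counterfactual output feeds the next
year's capital stock. `χ` defaults to 1.0 — every averted treatment dollar
is invested — which is deliberately an upper bound; the treatment-cost
channel share scales roughly linearly in `χ`, and a value near the saving
rate (`χ ≈ s`) is the natural lower-bound convention if freed resources
are split like other income. `χ` is a first-class configuration field.

**Partial elimination.** A reduction of prevalence by a factor `ρ < 1`
scales the removed mortality (`ρσ_r` in the population correction and in
the morbidity product), the averted caregiving, and the diverted treatment
cost `ρχTC` alike. This makes the burden exactly zero at `ρ = 0`, equal to
the full counterfactual at `ρ = 1`, and monotone in between (verified by
test). The closed-form labor approximation
`ΔL ≈ ℓn Σ_τ ρσ_r(1 + p^τ ξ)` is provided alongside the exact two-path
difference; on single-lineage cells with `σ_r ≤ 0.005` the two agree
within 5% (typically well under 1%). The closed form does not model the
pooled terminal age group and should not be applied to it.

**Burden accounting.** `total = Σ_t (Ȳ_t − Y_t)/(1+r)^(t−t₀)` with the
first horizon year undiscounted; main discount rate 2%, sensitivity 0% and
3%. The percent-of-GDP figure divides by the *undiscounted status-quo* GDP
sum over the horizon — this is the convention that makes the published
cross-table arithmetic consistent (a burden of 10,216 billion against an
annual-average GDP of 147,771 billion over 31 years is 0.223%), and the
per-capita figure divides by the annual-average population (the same
example gives INT$1,157 per person). Both identities are asserted in the
test suite.

**Channel decomposition** is ratio-of-reruns: the treatment-cost share is
the capital-channel-only burden over the all-channel burden excluding
informal care, the human-capital share the labor-channels-only burden over
the same denominator, and their shortfall from 1 is reported explicitly as
an interaction term rather than forced to zero. The informal-care share is
measured against the with-care total. With a zero reference burden the
shares are undefined and returned absent, with a warning.

**COVID-19 add-on.** Exogenous infection counts for 2020–2022 produce
(i) extra incident diabetes among 30-day infection survivors,
`infections·incidence·(HR−1)` with HR 1.40, persisting as prevalent
chronic cases that age with their cohorts and carry proportional
disability, treatment cost and caregiving; and (ii) extra deaths among
infected diabetic patients, `diabetics_infected·fatality·(3.6−1)`, capped
so total deaths never exceed the infected patient count. The scenario-3
economy is simulated under the *baseline-calibrated* TFP path (it is not
re-calibrated to the GDP projection, so the extra burden genuinely lowers
output), and the additional burden is the difference between the augmented
and baseline burdens under the shared elimination counterfactual. The
add-on never alters the baseline results (separation is tested). Whether
the mortality multiplier applies to all infected diabetics or only
hospitalized ones is a scope flag (`hospitalized_only` with a
`hospitalized_share`), defaulting to the general interpretation.

**Undiagnosed cases.** The sensitivity scenario charges undiagnosed
patients the diagnosed per-case treatment cost with no productivity gain:
the treatment-cost series is scaled by `1/(1−share)`.

**Imputation.** Countries with incomplete inputs get OLS-imputed burdens:
log per-capita burden on log GDP per capita and the disease DALY rate,
fitted on at least 10 complete countries, predictions clamped nonnegative
and flagged `imputed`. The exact covariate set of the original regression
is not public; this default is a documented, configurable stand-in.

**Aggregation.** Group figures (region, income group, world) are computed
from summed numerators and denominators — never averages of country
ratios — and low/high uncertainty bounds come from re-running the pipeline
on scaled epidemiological inputs, which brackets the mean run by
construction (monotonicity is tested, not assumed).

## Synthetic data

The generator emulates the statistical structure of real inputs so the
pipeline is testable without any external data: Gompertz all-cause
mortality (`level·e^{slope·age}`, defaults 5e−5 and 0.09, capped at 0.7)
with a ±5% sex differential; a cause-specific share ramping linearly over
ages 20–60 to a configurable fraction of all-cause deaths (default 3%, the
approximate share of deaths attributable to diabetes); a stationary
initial age structure projected forward with constant births; hump-shaped
participation (ramp over ages 15–25, plateau to 54, exponential decline
after, small positive tail above 65, zero from 90); geometric GDP growth
(default 3%/year); constant saving rate (0.22) and treatment-cost share of
GDP (0.8%); adult prevalence ramping to ~15% at older ages (10% base
rate). YLL is derived from simulated cause-specific deaths times residual
life expectancy to a reference age of 86 — a stand-in for a reference life
table, chosen so that `ξ` and `σ_r` are mutually consistent — and YLD is
`ξ·YLL` with `ξ` drawn uniformly per age from [0.5, 5].

What the generator does **not** emulate: time trends in mortality and
prevalence, migration, sex-specific epidemiology beyond a level shift,
business cycles in GDP or saving, and correlation between treatment cost
and income level. Passing tests therefore demonstrate the correctness of
the mechanics and accounting conventions on data with realistic structure,
not the reproduction of any real country's estimate.

The hand-coded toy fixture (3 age groups, 1 sex, 5 years, round numbers,
unit Mincer weights) exists for oracle tests where every number can be
recomputed by hand.

## Numerical choices

* Accumulated history products are evaluated by diagonal recursion (for
  the pure survival product) or an explicit O(T²) lag sweep (for the
  p-weighted morbidity product, which does not factorize); at 31 years ×
  101 ages × 2 sexes a full scenario pair runs in ~10 ms.
* Clipping contracts: counterfactual participation is capped at 1, care
  deductions at available labor, effective labor floored at 0, morbidity
  factors at 1−1e−9, the counterfactual saving rate at 1 — each clip is
  counted and logged, never silent.
* Degenerate cells: `ξ = 0` where YLL = YLD = 0; `ξ = xi_cap` where
  YLL = 0 < YLD; division guards raise `DomainError` rather than
  propagate NaN.
* Determinism: every stochastic element is driven by an explicit
  `numpy.random.default_rng` seed; fixed seed ⇒ bit-identical panels
  (checksum-tested).

## Problem sizes

The acceptance script runs 200 countries at full resolution (31 × 101 × 2)
with ~9 scenario evaluations per country (mean/low/high epidemiology,
with/without care, channel isolation, undiagnosed adjustment, COVID
add-on), completing in well under a minute on one CPU; the test suite uses
41–71-age panels for property tests and the full grid where the contract
concerns full resolution.

## Known limitations

* No general-equilibrium feedback: wages, participation preferences and
  budget reallocation are fixed; the estimates are partial-equilibrium.
* No migration or fertility response; births are identical across
  scenarios by assumption.
* The terminal age group is an absorbing pool; cohort-lineage formulas
  (the closed-form ΔL in particular) are inexact there.
* Indirect mortality through downstream conditions (e.g. cardiovascular
  disease caused by diabetes) is not attributed to the disease.
* `χ`, `p`, the caregiver age distribution and the imputation covariates
  are conventions where the underlying evidence is not determinative; all
  are exposed in configuration and documented above.
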