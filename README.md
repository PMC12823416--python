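# macroburden

Health-augmented macroeconomic projection of the GDP burden of a chronic
disease — built for diabetes mellitus — for epidemiologists and health
economists who need country-level, multi-decade burden estimates that
respect economic adjustment mechanisms rather than summing costs of
illness.

## The model

An economy produces output with a Cobb–Douglas technology

```
Y_t = A_t · K_t^α · H_t^(1−α)
```

where `K_t` is physical capital, evolving by `K_{t+1} = (1−δ)K_t + s_t Y_t`
with the saving rate defined net of disease treatment cost,
`s_t = 1 − (C_t + TC_t)/Y_t`, and `H_t` is aggregate human capital — the
sum of age–sex-specific effective labor weighted by Mincer human capital

```
H_t = Σ_a h_t^(a) ℓ_t^(a) n_t^(a),   h = exp[η₁·ys + η₂·x + η₃·x²],  x = a − ys − 5.
```

Total factor productivity `A_t` is calibrated so the status-quo run
reproduces the input GDP projection exactly, then held fixed in the
counterfactual where the disease is eliminated from the base year at zero
cost. Elimination acts through four channels:

* **mortality** — cohorts evolve under other-cause mortality `σ₋ᵣ`, where
  `(1−σ) = (1−σᵣ)(1−σ₋ᵣ)`, equivalently `n̄ = n / Π(1−σᵣ)` along cohort
  lineages;
* **morbidity** — survivors of averted disease regain participation,
  `ℓ̄ ≈ ℓ / Π(1 − pᵗ σᵣ ξ)` with the morbidity ratio `ξ = YLD/YLL`;
* **treatment cost** — a fraction `χ` of the averted cost `ρχ·TC_t` is
  diverted to investment each year;
* **informal care** — each prevalent patient costs `hours/workweek`
  (default 4.0/35.9 ≈ 0.11) units of caregiver labor, removed in
  proportion to elimination.

The burden is the discounted cumulative GDP gap
`Σ_t (Ȳ_t − Y_t)/(1+r)^(t−t₀)` over 2020–2050, reported in total INT$,
per capita, and as a percent of the horizon's GDP sum. A COVID-19 add-on
converts 2020–2022 infection counts into extra incident diabetes
(HR 1.40 among 30-day survivors) and extra deaths among infected patients
(3.6× relative risk) and measures the additional burden separately.
Countries with incomplete inputs are imputed from an OLS regression of log
per-capita burden on log GDP per capita and the disease DALY rate.

## Worked example

```python
from macroburden import (ScenarioConfig, SynthConfig, generate_country,
                         evaluate, decompose_channels)

inp = generate_country(SynthConfig(seed=42, name="demo"))
cfg = ScenarioConfig()                # rho=1, chi=1, r=2%, 4.0 h/week care
res = evaluate(inp, cfg)
print(f"burden total   : INT$ {res.total:,.0f} million")
print(f"per capita     : INT$ {res.per_capita:,.0f}")
print(f"percent of GDP : {res.pct_gdp:.3f} %")
for k, v in decompose_channels(inp, cfg).items():
    print(f"share {k:14s}: {100*v:.1f} %")
```

prints

```
burden total   : INT$ 213,015 million
per capita     : INT$ 21,297
percent of GDP : 2.130 %
share treatment_cost: 75.7 %
share human_capital : 24.1 %
share interaction   : 0.1 %
share informal_care : 59.7 %
```

The synthetic country (10 million people, INT$200 billion GDP, 10% adult
diabetes prevalence, treatment cost 0.8% of GDP) loses INT$213 billion of
discounted output over 2020–2050 — 2.13% of the horizon's GDP. Of the
burden excluding caregiving, 75.7% flows through the diversion of
treatment spending away from capital accumulation and 24.1% through
mortality/morbidity losses of human capital; informal caregiving, when
included, accounts for 59.7% of the with-care total. The treatment-cost
share is an upper bound under the default full diversion (`chi = 1`).

A command-line interface mirrors the library:

```
macroburden generate --seed 1 --out panel.csv
macroburden simulate --input panel.csv --scenario counterfactual --out paths.csv
macroburden burden   --input panel.csv --out burden.csv
macroburden sensitivity --input panel.csv --out sens.csv
```

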