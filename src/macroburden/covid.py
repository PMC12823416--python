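"""COVID-19 add-on.

SARS-CoV-2 infection raises the subsequent incidence of diabetes (hazard
ratio 1.40, 95% CI 1.36-1.44, among 30-day infection survivors) and raises
mortality among infected diabetic patients (3.6x relative death risk).
This module converts an exogenous infection series for 2020-2022 into
extra incident diabetes cases and extra diabetes deaths, builds an
augmented country panel in which those cases persist as prevalent chronic
cases (carrying proportional disability, treatment cost and caregiving),
and measures the additional macroeconomic burden over the full horizon.

The add-on is kept strictly separate from the baseline: the baseline
burden is computed from the unmodified panel, and the additional burden is
the difference between the augmented and baseline burdens under a shared
counterfactual (elimination also removes the COVID-attributable diabetes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import demography as dem
from .capital import step_capital
from .engine import (BurdenResult, ScenarioConfig, ScenarioResult, burden,
                     output, run_scenario)
from .exceptions import DomainError, ShapeError
from .human_capital import MincerParams, aggregate_H, mincer_h
from .panel import CountryInput

__all__ = ["CovidParams", "extra_incident_cases", "extra_diabetes_deaths", "covid_burden"]

logger = logging.getLogger(__name__)

INFECTION_WINDOW = ("2020-01-01", "2022-09-01")


@dataclass
class CovidParams:
    """COVID-to-diabetes transmission parameters.

    ``infections`` is a (years, ages) grid of infected persons per year
    (zero outside the 2020-2022 window); ``baseline_incidence`` the
    per-person-year incidence of diabetes by age; ``infected_fatality`` the
    baseline annual death risk of an infected diabetic patient, multiplied
    by ``mortality_multiplier`` when infected; ``acute_fatality`` the
    30-day acute case fatality (incident-diabetes risk applies to
    survivors only).
    """

    infections: np.ndarray
    baseline_incidence: np.ndarray
    hr_incident: float = 1.40
    mortality_multiplier: float = 3.6
    infected_fatality: float = 0.02
    acute_fatality: float = 0.0
    infection_window: tuple[str, str] = INFECTION_WINDOW
    hospitalized_only: bool = False  # scope flag for the mortality multiplier
    hospitalized_share: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.infections = np.asarray(self.infections, dtype=float)
        self.baseline_incidence = np.asarray(self.baseline_incidence, dtype=float)
        if self.hr_incident < 1.0:
            raise DomainError("hr_incident must be >= 1")
        if self.mortality_multiplier < 1.0:
            raise DomainError("mortality_multiplier must be >= 1")
        if np.any(self.infections < 0):
            raise DomainError("infections must be nonnegative")
        if np.any(self.baseline_incidence < 0) or np.any(self.baseline_incidence > 1):
            raise DomainError("baseline incidence must lie in [0, 1]")
        if not 0.0 <= self.acute_fatality <= 1.0:
            raise DomainError("acute_fatality must lie in [0, 1]")


def extra_incident_cases(infections, incidence, hr):
    """Extra incident diabetes cases among infection survivors.

    ``extra = infections * incidence * (hr - 1)`` — the excess over the
    baseline incidence those people would have had anyway.
    """
    if np.any(np.asarray(hr) < 1.0):
        raise DomainError("hazard ratio must be >= 1")
    infections = np.asarray(infections, dtype=float)
    incidence = np.asarray(incidence, dtype=float)
    if np.any(incidence < 0) or np.any(incidence > 1):
        raise DomainError("incidence must lie in [0, 1]")
    out = infections * incidence * (hr - 1.0)
    return float(out) if out.ndim == 0 else out


def extra_diabetes_deaths(diabetics_infected, baseline_fatality, multiplier):
    """Extra deaths among infected diabetic patients, capped at the number
    of patients.

    ``extra = diabetics_infected * baseline_fatality * (multiplier - 1)``,
    with total deaths (baseline + extra) never exceeding the infected
    patient count.
    """
    if np.any(np.asarray(multiplier) < 1.0):
        raise DomainError("mortality multiplier must be >= 1")
    d = np.asarray(diabetics_infected, dtype=float)
    f = np.asarray(baseline_fatality, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise DomainError("baseline fatality must lie in [0, 1]")
    extra = d * f * (multiplier - 1.0)
    cap = d * (1.0 - f)  # total deaths <= diabetics_infected
    out = np.minimum(extra, np.maximum(cap, 0.0))
    return float(out) if out.ndim == 0 else out


def _augment_input(inp: CountryInput, params: CovidParams) -> tuple[CountryInput, np.ndarray]:
    """Panel with COVID-attributable extra prevalence and mortality folded in.

    Returns the augmented panel and the extra death-rate grid ``q`` used to
    shrink the scenario-3 population.
    """
    T, A = inp.n_years, len(inp.ages)
    if params.infections.shape != (T, A):
        raise ShapeError(f"infections must have shape ({T}, {A})")
    if params.baseline_incidence.shape != (A,):
        raise ShapeError(f"baseline_incidence must have shape ({A},)")

    pop_age = inp.population.sum(axis=2)
    safe_pop = np.maximum(pop_age, 1e-12)

    # extra incident cases, aging with their cohorts and thinned by
    # all-cause survival (chronic: they persist for the rest of the horizon)
    survivors = params.infections * (1.0 - params.acute_fatality)
    new_cases = extra_incident_cases(survivors, params.baseline_incidence[None, :],
                                     params.hr_incident)
    sigma_mean = 1.0 - (1.0 - inp.all_cause_mortality).prod(axis=2) ** (1.0 / inp.population.shape[2])
    extra_prev = np.zeros((T, A))
    extra_prev[0] = new_cases[0]
    for t in range(1, T):
        aged = extra_prev[t - 1] * (1.0 - sigma_mean[t - 1])
        extra_prev[t, 1:] = aged[:-1]
        extra_prev[t, -1] += aged[-1]
        extra_prev[t] += new_cases[t]
    extra_prev = np.minimum(extra_prev, np.maximum(pop_age - inp.prevalence, 0.0))

    # extra deaths among infected diabetic patients
    share = params.hospitalized_share if params.hospitalized_only else 1.0
    diabetics_infected = params.infections * (inp.prevalence / safe_pop) * share
    extra_d = extra_diabetes_deaths(diabetics_infected, params.infected_fatality,
                                    params.mortality_multiplier)
    q = np.clip(extra_d / safe_pop, 0.0, 0.99)  # extra death rate by year/age

    # fold into the rate grids multiplicatively (keeps sigma_r <= sigma)
    q3 = q[:, :, None]
    sigma_new = 1.0 - (1.0 - inp.all_cause_mortality) * (1.0 - q3)
    sigma_r_new = 1.0 - (1.0 - inp.diabetes_mortality) * (1.0 - q3)

    prev_new = inp.prevalence + extra_prev
    prev_ratio = np.where(inp.prevalence > 0, prev_new / np.maximum(inp.prevalence, 1e-12), 1.0)
    yld_new = inp.yld * prev_ratio
    rle = np.maximum(86.0 - inp.ages, 0.5)
    yll_new = inp.yll + extra_d * rle[None, :]
    tot_prev = inp.prevalence.sum(axis=1)
    tc_ratio = np.where(tot_prev > 0, prev_new.sum(axis=1) / np.maximum(tot_prev, 1e-12), 1.0)
    tc_new = inp.treatment_cost * tc_ratio

    aug = inp.replace(
        all_cause_mortality=sigma_new,
        diabetes_mortality=sigma_r_new,
        prevalence=prev_new,
        yld=yld_new,
        yll=yll_new,
        treatment_cost=tc_new,
    )
    return aug, q


def _simulate_under_tfp(inp: CountryInput, aug: CountryInput, cfg: ScenarioConfig,
                        A_path: np.ndarray, q: np.ndarray) -> ScenarioResult:
    """Scenario-3 run: augmented disease burden under the baseline TFP path.

    Population is the status-quo grid thinned by the accumulated extra
    death rate; participation carries the extra morbidity correction; the
    extra treatment cost crowds out investment by ``chi`` per unit.
    """
    T = inp.n_years
    q3 = np.repeat(q[:, :, None], inp.population.shape[2], axis=2)
    shrink = dem._cohort_survival_product(q3)
    n_aug = inp.population * shrink

    xi = dem.morbidity_ratio(aug.yld, aug.yll, cfg.xi_cap)
    extra_morb = dem._history_terms(q3, xi, cfg.p, 1.0, "product", clip=True)
    l_aug = inp.participation * extra_morb

    from .engine import _caregiver_weights
    w = _caregiver_weights(inp)
    informal = None
    if cfg.channels.informal_care and cfg.care_hours > 0:
        informal = np.vstack([
            dem.informal_care_deduction(aug.prevalence[t], cfg.care_hours, cfg.workweek, w)
            for t in range(T)
        ])
    L = dem.effective_labor(dem.CohortGrid(n_aug, "status_quo"), l_aug, informal)
    h = mincer_h(
        np.broadcast_to(inp.ages.astype(float)[None, :, None], inp.schooling.shape),
        inp.schooling, MincerParams(inp.eta1, inp.eta2, inp.eta3),
    )
    H = aggregate_H(h, L)

    K = np.empty(T)
    Y = np.empty(T)
    K[0] = inp.capital0
    extra_tc = aug.treatment_cost - inp.treatment_cost if cfg.channels.treatment_cost else np.zeros(T)
    for t in range(T):
        Y[t] = output(A_path[t], K[t], H[t], inp.alpha)
        if t + 1 < T:
            K[t + 1] = max(step_capital(K[t], Y[t], inp.saving_rate[t], inp.delta)
                           - cfg.chi * extra_tc[t], 0.0)
    return ScenarioResult(inp.years, Y, K, H, A_path.copy(), L.sum(axis=(1, 2)),
                          "covid_status_quo")


def covid_burden(inp: CountryInput, params: CovidParams,
                 cfg: ScenarioConfig) -> BurdenResult:
    """Additional burden attributable to COVID-driven diabetes.

    Difference between the burden of the augmented panel and the baseline
    burden, both measured against the shared elimination counterfactual
    under the baseline-calibrated TFP path.
    """
    sq = run_scenario(inp, cfg, "status_quo")
    cf = run_scenario(inp, cfg, "counterfactual")
    pop = inp.population.sum(axis=(1, 2))

    aug, q = _augment_input(inp, params)
    sq_aug = _simulate_under_tfp(inp, aug, cfg, sq.A, q)

    b_base = burden(sq, cf, cfg.discount_rate, pop, inp.gdp)
    b_aug = burden(sq_aug, cf, cfg.discount_rate, pop, inp.gdp)
    diff = b_aug.by_year - b_base.by_year
    return BurdenResult(
        total=b_aug.total - b_base.total,
        per_capita=b_aug.per_capita - b_base.per_capita,
        pct_gdp=b_aug.pct_gdp - b_base.pct_gdp,
        by_year=diff,
        discount_rate=cfg.discount_rate,
    )
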