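"""Scenario engine.

Ties demography, human capital and capital accumulation into the
Cobb-Douglas production function ``Y = A * K**alpha * H**(1-alpha)``,
calibrates total factor productivity A so the status-quo run reproduces the
input GDP projection exactly, and measures the disease burden as the
discounted cumulative GDP gap between the status-quo and the
disease-elimination counterfactual.

The counterfactual holds the calibrated A fixed (technology is exogenous,
unaffected by disease) and differs through three channels plus informal
care:

* mortality  -- population projected under other-cause mortality only;
* morbidity  -- participation raised by the accumulated morbidity
  correction (xi = YLD/YLL);
* treatment_cost -- a fraction chi of the averted treatment cost is
  diverted to investment each year;
* informal_care  -- the caregiving deduction from effective labor shrinks
  in proportion to the eliminated prevalence.

A partial elimination by ``rho`` scales the removed cause-specific
mortality, the morbidity correction, the averted caregiving and the
diverted treatment cost all by ``rho``, so the burden is 0 at rho = 0 and
reaches the full counterfactual gap at rho = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import demography as dem
from .capital import capital_path, counterfactual_saving, step_capital
from .exceptions import DomainError, ShapeError
from .human_capital import MincerParams, aggregate_H, mincer_h
from .panel import CountryInput
from .reporting import per_capita, percent_of_gdp

__all__ = [
    "Channels",
    "ScenarioConfig",
    "ScenarioResult",
    "BurdenResult",
    "output",
    "calibrate_tfp",
    "run_scenario",
    "burden",
    "evaluate",
    "decompose_channels",
    "sensitivity_suite",
    "undiagnosed_adjustment",
    "epidemiology_variant",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Channels:
    """Toggles for the effect pathways of the counterfactual."""

    mortality: bool = True
    morbidity: bool = True
    treatment_cost: bool = True
    informal_care: bool = True


@dataclass(frozen=True)
class ScenarioConfig:
    rho: float = 1.0            # fraction of prevalence/mortality eliminated
    chi: float = 1.0            # averted treatment cost diverted to saving
    discount_rate: float = 0.02
    care_hours: float = 4.0     # weekly informal care hours per patient
    workweek: float = 35.9      # full-time weekly work hours
    p: float = 1.0              # survivor morbidity persistence weight
    xi_cap: float = 10.0        # cap for YLD/YLL where YLL = 0
    channels: Channels = field(default_factory=Channels)
    undiagnosed_share: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("rho", "chi", "p"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{nm} must lie in [0, 1]; got {v}")
        if self.discount_rate < 0:
            raise DomainError("discount_rate must be nonnegative")
        if not 0.0 <= self.care_hours <= self.workweek:
            raise DomainError("care_hours must lie in [0, workweek]")
        if not 0.0 <= self.undiagnosed_share < 1.0:
            raise DomainError("undiagnosed_share must lie in [0, 1)")


@dataclass
class ScenarioResult:
    years: np.ndarray
    Y: np.ndarray  # output, INT$ millions
    K: np.ndarray  # capital
    H: np.ndarray  # aggregate human capital
    A: np.ndarray  # TFP
    L: np.ndarray  # total effective labor per year
    scenario_label: str


@dataclass
class BurdenResult:
    total: float          # discounted cumulative GDP gap, INT$ millions
    per_capita: float     # INT$ per person (against annual-average population)
    pct_gdp: float        # percent of undiscounted status-quo GDP sum
    by_year: np.ndarray   # undiscounted yearly GDP gaps
    discount_rate: float
    channel_shares: dict | None = None


# ---------------------------------------------------------------------------
# production function and TFP calibration

def output(A, K, H, alpha):
    """Cobb-Douglas output ``Y = A * K**alpha * H**(1-alpha)``."""
    if not 0.0 <= alpha <= 1.0:
        raise DomainError("alpha must lie in [0, 1]")
    A, K, H = (np.asarray(v, dtype=float) for v in (A, K, H))
    if np.any(A < 0) or np.any(K < 0) or np.any(H < 0):
        raise DomainError("A, K and H must be nonnegative")
    Y = A * K ** alpha * H ** (1.0 - alpha)
    return float(Y) if Y.ndim == 0 else Y


def calibrate_tfp(Y_proj, K, H, alpha):
    """Back out the TFP path from a GDP projection: ``A = Y / (K**a H**(1-a))``."""
    Y_proj, K, H = (np.asarray(v, dtype=float) for v in (Y_proj, K, H))
    if np.any(K <= 0) or np.any(H <= 0):
        raise DomainError("calibration requires strictly positive K and H")
    A = Y_proj / (K ** alpha * H ** (1.0 - alpha))
    return float(A) if A.ndim == 0 else A


# ---------------------------------------------------------------------------
# scenario machinery

def _mincer_grid(inp: CountryInput) -> np.ndarray:
    params = MincerParams(inp.eta1, inp.eta2, inp.eta3)
    age_grid = np.broadcast_to(
        inp.ages.astype(float)[None, :, None], inp.schooling.shape
    )
    return mincer_h(age_grid, inp.schooling, params)


def _caregiver_weights(inp: CountryInput) -> np.ndarray:
    """Default caregiver age distribution: proportional to status-quo
    effective labor across working ages (overridable per input)."""
    if inp.caregiver_weights is not None:
        return inp.caregiver_weights
    labor = (inp.participation * inp.population).sum(axis=(0, 2))
    tot = labor.sum()
    if tot <= 0:
        raise DomainError("cannot derive caregiver weights: no effective labor")
    return labor / tot


def _informal_grid(inp: CountryInput, cfg: ScenarioConfig, scale: float = 1.0) -> np.ndarray | None:
    """(T, A) informal-care labor deduction, or None when the channel is off."""
    if not cfg.channels.informal_care or cfg.care_hours == 0 or scale == 0:
        return None
    w = _caregiver_weights(inp)
    rows = [
        dem.informal_care_deduction(inp.prevalence[t] * scale, cfg.care_hours,
                                    cfg.workweek, w)
        for t in range(inp.n_years)
    ]
    return np.vstack(rows)


def _status_quo(inp: CountryInput, cfg: ScenarioConfig) -> ScenarioResult:
    grid = inp.population_grid()
    informal = _informal_grid(inp, cfg)
    L = dem.effective_labor(grid, inp.participation, informal)
    h = _mincer_grid(inp)
    H = aggregate_H(h, L)
    K = capital_path(inp.capital0, inp.gdp, inp.saving_rate, inp.delta)
    A = calibrate_tfp(inp.gdp, K, H, inp.alpha)
    return ScenarioResult(inp.years, inp.gdp.copy(), K, H, A,
                          L.sum(axis=(1, 2)), "status_quo")


def _counterfactual(inp: CountryInput, cfg: ScenarioConfig,
                    sq: ScenarioResult) -> ScenarioResult:
    ch = cfg.channels
    xi = dem.morbidity_ratio(inp.yld, inp.yll, cfg.xi_cap)

    rho_mort = cfg.rho if ch.mortality else 0.0
    nbar = dem.counterfactual_population(
        inp.population_grid(), inp.diabetes_mortality, rho=rho_mort,
        all_cause_mortality=inp.all_cause_mortality,
    )
    if ch.morbidity:
        lbar = dem.counterfactual_participation(
            inp.participation, inp.diabetes_mortality, xi, cfg.p, rho=cfg.rho
        )
    else:
        lbar = inp.participation
    informal = _informal_grid(inp, cfg, scale=1.0 - cfg.rho)
    Lbar = dem.effective_labor(nbar, lbar, informal)
    h = _mincer_grid(inp)
    Hbar = aggregate_H(h, Lbar)

    T = inp.n_years
    Kbar = np.empty(T)
    Ybar = np.empty(T)
    Kbar[0] = inp.capital0
    tc = inp.treatment_cost if ch.treatment_cost else np.zeros(T)
    for t in range(T):
        Ybar[t] = output(sq.A[t], Kbar[t], Hbar[t], inp.alpha)
        if t + 1 < T:
            sbar = counterfactual_saving(inp.saving_rate[t], Ybar[t], tc[t],
                                         cfg.chi, cfg.rho)
            Kbar[t + 1] = step_capital(Kbar[t], Ybar[t], sbar, inp.delta)
    return ScenarioResult(inp.years, Ybar, Kbar, Hbar, sq.A.copy(),
                          Lbar.sum(axis=(1, 2)), "counterfactual")


def run_scenario(inp: CountryInput, cfg: ScenarioConfig, which: str) -> ScenarioResult:
    """Run one scenario.

    ``which = "status_quo"`` reproduces the input GDP projection exactly
    (TFP calibration); ``which = "counterfactual"`` reruns the economy with
    the disease (partially) eliminated, feeding each year's counterfactual
    output into next year's capital stock.
    """
    if which not in ("status_quo", "counterfactual"):
        raise DomainError(f"unknown scenario {which!r}")
    sq = _status_quo(inp, cfg)
    if which == "status_quo":
        return sq
    return _counterfactual(inp, cfg, sq)


def burden(sq: ScenarioResult, cf: ScenarioResult, r: float,
           pop: np.ndarray, gdp: np.ndarray) -> BurdenResult:
    """Discounted cumulative GDP gap between counterfactual and status quo.

    ``total = sum_t (Ybar_t - Y_t) / (1 + r)**(t - t0)`` with the first
    horizon year as base, in INT$ millions; the percent-of-GDP denominator
    is the undiscounted status-quo GDP sum over the horizon, and the
    per-capita figure (INT$ per person) divides by the annual-average
    population in persons.
    """
    if sq.Y.shape != cf.Y.shape or len(pop) != len(sq.Y) or len(gdp) != len(sq.Y):
        raise ShapeError("scenario horizons and denominators must align")
    diff = cf.Y - sq.Y
    disc = (1.0 + r) ** np.arange(len(diff))
    total = float(np.sum(diff / disc))
    return BurdenResult(
        total=total,
        per_capita=per_capita(total * 1e6, pop),
        pct_gdp=percent_of_gdp(total, gdp),
        by_year=diff,
        discount_rate=r,
    )


def evaluate(inp: CountryInput, cfg: ScenarioConfig) -> BurdenResult:
    """Run both scenarios and return the burden for one country."""
    sq = run_scenario(inp, cfg, "status_quo")
    cf = run_scenario(inp, cfg, "counterfactual")
    pop = inp.population.sum(axis=(1, 2))
    return burden(sq, cf, cfg.discount_rate, pop, inp.gdp)


# ---------------------------------------------------------------------------
# decomposition, sensitivity, adjustments

def _with_channels(cfg: ScenarioConfig, **flags) -> ScenarioConfig:
    base = dict(mortality=False, morbidity=False, treatment_cost=False,
                informal_care=False)
    base.update(flags)
    return replace(cfg, channels=Channels(**base))


def decompose_channels(inp: CountryInput, cfg: ScenarioConfig) -> dict:
    """Channel decomposition by ratio of re-runs.

    The treatment-cost share is the capital-channel-only burden over the
    all-channel burden excluding informal care; the human-capital share the
    labor-channels-only burden over the same denominator; their shortfall
    from 1 is reported explicitly as ``interaction``. The informal-care
    share is measured against the with-care total. Returns an empty dict
    (with a warning) when the reference burden is zero.
    """
    b_core = evaluate(inp, _with_channels(cfg, mortality=True, morbidity=True,
                                          treatment_cost=True)).total
    if abs(b_core) <= 1e-9 * inp.gdp.sum():
        logger.warning("zero all-channel burden: channel shares undefined")
        return {}
    b_tc = evaluate(inp, _with_channels(cfg, treatment_cost=True)).total
    b_hc = evaluate(inp, _with_channels(cfg, mortality=True, morbidity=True)).total
    shares = {
        "treatment_cost": b_tc / b_core,
        "human_capital": b_hc / b_core,
    }
    shares["interaction"] = 1.0 - shares["treatment_cost"] - shares["human_capital"]
    b_all = evaluate(inp, _with_channels(cfg, mortality=True, morbidity=True,
                                         treatment_cost=True, informal_care=True)).total
    shares["informal_care"] = (b_all - b_core) / b_all if b_all > 0 else 0.0
    return shares


def epidemiology_variant(inp: CountryInput, factor: float) -> CountryInput:
    """Scale the cause-specific mortality and morbidity inputs by ``factor``.

    Emulates the lower/upper uncertainty bounds of the epidemiological
    sources; cause-specific mortality is clipped to stay below all-cause
    mortality.
    """
    if factor < 0:
        raise DomainError("epidemiology factor must be nonnegative")
    sig_r = np.minimum(inp.diabetes_mortality * factor, inp.all_cause_mortality)
    return inp.replace(
        diabetes_mortality=sig_r,
        yll=inp.yll * factor,
        yld=inp.yld * factor,
    )


def sensitivity_suite(
    inputs: CountryInput | dict,
    base_cfg: ScenarioConfig,
    discount_rates=(0.0, 0.02, 0.03),
    care_hours=(0.285, 4.0, 8.3),
) -> pd.DataFrame:
    """Burden grid over discount rate, weekly care hours and epi variants.

    ``inputs`` may be a single panel (labelled ``mean``) or a dict with
    keys among ``low``/``mean``/``high`` carrying epidemiological variants.
    """
    if isinstance(inputs, CountryInput):
        inputs = {"mean": inputs}
    rows = []
    for epi, inp in inputs.items():
        for r in discount_rates:
            for hours in care_hours:
                cfg = replace(base_cfg, discount_rate=r, care_hours=hours)
                res = evaluate(inp, cfg)
                rows.append({
                    "epi": epi, "discount_rate": r, "care_hours": hours,
                    "total": res.total, "pct_gdp": res.pct_gdp,
                    "per_capita": res.per_capita,
                })
    return pd.DataFrame(rows)


def undiagnosed_adjustment(inp: CountryInput, share: float) -> CountryInput:
    """Extend the diagnosed per-case treatment cost to undiagnosed patients.

    With a fraction ``share`` of cases undiagnosed and costless, charging
    them the same per-case cost scales the treatment-cost series by
    ``1 / (1 - share)`` while leaving everything else unchanged.
    """
    if not 0.0 <= share < 1.0:
        raise DomainError("undiagnosed share must lie in [0, 1)")
    return inp.replace(treatment_cost=inp.treatment_cost / (1.0 - share))
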