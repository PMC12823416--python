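"""Synthetic country panels.

Real applications of the model assemble each country's inputs from
demographic, epidemiological, labor-force, education and national-accounts
sources. This module generates panels with the same statistical structure —
Gompertz-type age-increasing mortality with a cause-specific component,
hump-shaped age profiles of labor-force participation, YLD/YLL ratios of
order 0.5-5, geometric GDP growth, saving rates and treatment-cost shares
in realistic ranges — so every downstream stage is testable without any
external data, plus a tiny hand-coded deterministic fixture for oracle
tests.

The generated population grid is itself produced by the cohort-component
recursion under the generated mortality, with births held constant at the
first-year age-0 count, so the demographic inputs are internally
consistent. YLL is derived from simulated cause-specific deaths times
residual life expectancy to a fixed reference age, which keeps the
morbidity ratio xi = YLD/YLL and the cause-specific mortality mutually
consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import project_population
from .exceptions import ValidationError
from .panel import CountryInput

__all__ = ["SynthConfig", "generate_country", "toy_country"]

#: reference age for residual life expectancy when converting deaths to YLL
YLL_REFERENCE_AGE = 86


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs for one synthetic country.

    Defaults describe a mid-sized middle-income country: 10 million people,
    INT$200 billion GDP growing 3% per year, diabetes causing ~3% of adult
    deaths, 10% adult prevalence, treatment costs 0.8% of GDP.
    """

    name: str = "synthetic"
    n_ages: int = 101                    # single-year ages 0..100
    years: tuple[int, int] = (2020, 2050)
    sexes: tuple[str, ...] = ("female", "male")
    gdp0: float = 200_000.0              # INT$ millions
    gdp_growth: float = 0.03
    pop0: float = 10_000_000.0
    mortality_level: float = 5e-5        # Gompertz level
    mortality_slope: float = 0.09        # Gompertz slope per year of age
    diabetes_mortality_share: float = 0.03
    yld_yll_ratio_range: tuple[float, float] = (0.5, 5.0)
    participation_peak: float = 0.85
    schooling_mean: float = 10.0
    saving_rate: float = 0.22
    tc_share_gdp: float = 0.008
    prevalence_rate: float = 0.10
    alpha: float = 1.0 / 3.0
    delta: float = 0.05
    eta1: float = 0.08
    eta2: float = 0.03
    eta3: float = -0.0003
    seed: int = 0

    def validate(self) -> None:
        if self.n_ages < 3:
            raise ValidationError("n_ages must be at least 3")
        if self.years[1] - self.years[0] < 1:
            raise ValidationError("years must span at least 2 years")
        fractions = ("gdp_growth", "participation_peak", "saving_rate",
                     "tc_share_gdp", "prevalence_rate", "alpha", "delta")
        for nm in fractions:
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{nm} must lie in [0, 1]; got {v}")
        if not 0.0 <= self.diabetes_mortality_share < 1.0:
            raise ValidationError(
                f"diabetes_mortality_share must lie in [0, 1); got {self.diabetes_mortality_share}"
            )
        lo, hi = self.yld_yll_ratio_range
        if lo < 0 or hi < lo:
            raise ValidationError(f"yld_yll_ratio_range must be ordered nonnegative; got {lo, hi}")
        if self.mortality_level < 0 or self.mortality_slope < 0:
            raise ValidationError("mortality_level and mortality_slope must be nonnegative")
        for nm in ("gdp0", "pop0", "schooling_mean"):
            if getattr(self, nm) < 0:
                raise ValidationError(f"{nm} must be nonnegative")


def _participation_profile(ages: np.ndarray, peak: float) -> np.ndarray:
    """Hump-shaped participation: ramp in 15-25, plateau to 54, decline
    after, small positive tail above 65."""
    lf = np.zeros_like(ages, dtype=float)
    ramp = (ages >= 15) & (ages < 25)
    lf[ramp] = peak * (ages[ramp] - 14) / 11.0
    lf[(ages >= 25) & (ages <= 54)] = peak
    old = ages > 54
    lf[old] = np.maximum(peak * np.exp(-0.09 * (ages[old] - 54)), 0.02)
    lf[ages >= 90] = 0.0
    return np.clip(lf, 0.0, 1.0)


def generate_country(cfg: SynthConfig) -> CountryInput:
    """Generate one internally consistent synthetic country panel."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    y0, y1 = cfg.years
    years = np.arange(y0, y1 + 1)
    T = len(years)
    ages = np.arange(cfg.n_ages)
    A, S = cfg.n_ages, len(cfg.sexes)

    # --- mortality: Gompertz in age, mild sex differential, flat in time
    base = np.clip(cfg.mortality_level * np.exp(cfg.mortality_slope * ages), 0.0, 0.7)
    sex_mult = np.linspace(0.95, 1.05, S) if S > 1 else np.array([1.0])
    sigma = np.clip(base[None, :, None] * sex_mult[None, None, :], 0.0, 0.7)
    sigma = np.broadcast_to(sigma, (T, A, S)).copy()

    # cause-specific share ramps in over adult ages
    adult_ramp = np.clip((ages - 20) / 40.0, 0.0, 1.0)
    sigma_r = cfg.diabetes_mortality_share * adult_ramp[None, :, None] * sigma

    # --- population: stationary age structure projected forward
    surv = np.cumprod(1.0 - base)
    struct = np.concatenate([[1.0], surv[:-1]])
    n0_age = cfg.pop0 * struct / struct.sum()
    n0 = np.repeat(n0_age[:, None], S, axis=1) / S
    births = n0[0]  # constant birth inflow per sex
    grid = project_population(n0, sigma, np.broadcast_to(births, (T, S)))
    population = grid.counts

    # --- labor and education
    lf = _participation_profile(ages, cfg.participation_peak)
    part_sex = np.linspace(0.9, 1.0, S) if S > 1 else np.array([1.0])
    participation = np.clip(
        np.broadcast_to(lf[None, :, None] * part_sex[None, None, :], (T, A, S)), 0, 1
    ).copy()
    ys = np.minimum(np.minimum(cfg.schooling_mean, np.maximum(ages - 5, 0)), 18.0)
    schooling = np.broadcast_to(ys[None, :, None], (T, A, S)).astype(float).copy()

    # --- macro series
    gdp = cfg.gdp0 * (1.0 + cfg.gdp_growth) ** np.arange(T)
    saving = np.full(T, cfg.saving_rate)
    tc = cfg.tc_share_gdp * gdp

    # --- epidemiology
    pop_age = population.sum(axis=2)
    prev_ramp = np.clip((ages - 20) / 30.0, 0.0, 1.0) * 1.5
    prevalence = np.minimum(cfg.prevalence_rate * prev_ramp[None, :] * pop_age, pop_age)

    deaths = (sigma_r * population).sum(axis=2)
    rle = np.maximum(YLL_REFERENCE_AGE - ages, 0.5)
    yll = deaths * rle[None, :]
    lo, hi = cfg.yld_yll_ratio_range
    xi_draw = rng.uniform(lo, hi, size=A)
    yld = xi_draw[None, :] * yll

    return CountryInput(
        name=cfg.name,
        years=years,
        ages=ages,
        sexes=list(cfg.sexes),
        population=population,
        all_cause_mortality=sigma,
        diabetes_mortality=sigma_r,
        yll=yll,
        yld=yld,
        participation=participation,
        schooling=schooling,
        gdp=gdp,
        saving_rate=saving,
        treatment_cost=tc,
        prevalence=prevalence,
        capital0=3.0 * cfg.gdp0,
        alpha=cfg.alpha,
        delta=cfg.delta,
        eta1=cfg.eta1,
        eta2=cfg.eta2,
        eta3=cfg.eta3,
    )


def toy_country() -> CountryInput:
    """Deterministic three-age micro-fixture for oracle tests.

    One sex, 5 years, ages standing in for children / workers / retirees,
    round numbers throughout: workers face all-cause mortality 0.02 of
    which 0.005 is disease-specific, the morbidity ratio is 0.5 and
    treatment costs are a constant 10 against a GDP of 1000 per year.
    The Mincer semi-elasticities are zero so every worker carries one unit
    of human capital.
    """
    years = np.arange(2020, 2025)
    ages = np.array([10, 40, 70])
    T, A, S = len(years), len(ages), 1

    sigma = np.broadcast_to(np.array([0.005, 0.02, 0.10])[None, :, None], (T, A, S)).copy()
    sigma_r = np.broadcast_to(np.array([0.0, 0.005, 0.02])[None, :, None], (T, A, S)).copy()

    n0 = np.array([[400.0], [1000.0], [200.0]])
    grid = project_population(n0, sigma, np.full((T, S), 400.0))
    population = grid.counts

    participation = np.broadcast_to(np.array([0.0, 0.8, 0.1])[None, :, None], (T, A, S)).copy()
    schooling = np.zeros((T, A, S))

    pop_age = population.sum(axis=2)
    prevalence = np.zeros((T, A))
    prevalence[:, 1] = np.minimum(100.0, pop_age[:, 1])

    deaths = (sigma_r * population).sum(axis=2)
    rle = np.maximum(YLL_REFERENCE_AGE - ages, 0.5)
    yll = deaths * rle[None, :]
    yld = 0.5 * yll

    return CountryInput(
        name="toy",
        years=years,
        ages=ages,
        sexes=["all"],
        population=population,
        all_cause_mortality=sigma,
        diabetes_mortality=sigma_r,
        yll=yll,
        yld=yld,
        participation=participation,
        schooling=schooling,
        gdp=np.full(T, 1000.0),
        saving_rate=np.full(T, 0.2),
        treatment_cost=np.full(T, 10.0),
        prevalence=prevalence,
        capital0=3000.0,
        alpha=1.0 / 3.0,
        delta=0.05,
        eta1=0.0,
        eta2=0.0,
        eta3=0.0,
    )
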