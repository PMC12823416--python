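"""Country panel containers.

A :class:`CountryInput` bundles everything the projection needs for one
country: the year x age x sex demographic and labor grids, the year x age
epidemiological grids (diabetes YLL/YLD and prevalent cases), the yearly
macro series (GDP projection, saving rate, treatment cost) and the model
scalars (initial capital stock K0, output elasticity alpha, depreciation
delta, Mincer semi-elasticities eta1..eta3).

Conventions
-----------
* years are calendar years, contiguous and increasing;
* ages are completed years (integers, 0-based), single-year resolution with
  a closed terminal group;
* all mortality rates are annual probabilities in [0, 1);
* money is in millions of 2017 international dollars unless stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ShapeError, ValidationError

__all__ = ["CountryInput", "CohortGrid"]


@dataclass
class CohortGrid:
    """Population counts on a year x age x sex grid for one scenario.

    ``scenario_label`` is ``"status_quo"`` or ``"counterfactual"``.
    """

    counts: np.ndarray
    scenario_label: str = "status_quo"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ShapeError(
                f"CohortGrid counts must be (year, age, sex); got ndim={self.counts.ndim}"
            )
        if np.any(self.counts < 0):
            raise ValidationError("CohortGrid counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def totals(self) -> np.ndarray:
        """Total population per year (summed over ages and sexes)."""
        return self.counts.sum(axis=(1, 2))


def _as2d(x, T, A, name):
    x = np.asarray(x, dtype=float)
    if x.shape != (T, A):
        raise ShapeError(f"{name} must have shape (years={T}, ages={A}); got {x.shape}")
    return x


def _as3d(x, T, A, S, name):
    x = np.asarray(x, dtype=float)
    if x.shape != (T, A, S):
        raise ShapeError(
            f"{name} must have shape (years={T}, ages={A}, sexes={S}); got {x.shape}"
        )
    return x


def _as1d(x, T, name):
    x = np.asarray(x, dtype=float)
    if x.shape != (T,):
        raise ShapeError(f"{name} must have shape (years={T},); got {x.shape}")
    return x


@dataclass
class CountryInput:
    """Full per-country model input panel.

    Grids are indexed ``[year, age]`` or ``[year, age, sex]`` matching
    ``years``/``ages``/``sexes``. ``yll``/``yld``/``prevalence`` are kept
    sex-aggregated because the morbidity ratio xi = YLD/YLL enters the model
    per age group only.
    """

    name: str
    years: np.ndarray
    ages: np.ndarray
    sexes: Sequence[str]
    population: np.ndarray          # (T, A, S) persons
    all_cause_mortality: np.ndarray  # (T, A, S) annual probability
    diabetes_mortality: np.ndarray   # (T, A, S) annual probability
    yll: np.ndarray                 # (T, A) years of life lost
    yld: np.ndarray                 # (T, A) years lived with disability
    participation: np.ndarray       # (T, A, S) fraction
    schooling: np.ndarray           # (T, A, S) years
    gdp: np.ndarray                 # (T,) INT$ millions
    saving_rate: np.ndarray         # (T,) fraction
    treatment_cost: np.ndarray      # (T,) INT$ millions
    prevalence: np.ndarray          # (T, A) diabetic persons
    capital0: float                 # INT$ millions
    alpha: float
    delta: float
    eta1: float
    eta2: float
    eta3: float
    caregiver_weights: np.ndarray | None = field(default=None)  # optional (A,) override

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=int)
        T, A, S = len(self.years), len(self.ages), len(self.sexes)
        self.population = _as3d(self.population, T, A, S, "population")
        self.all_cause_mortality = _as3d(self.all_cause_mortality, T, A, S, "all_cause_mortality")
        self.diabetes_mortality = _as3d(self.diabetes_mortality, T, A, S, "diabetes_mortality")
        self.participation = _as3d(self.participation, T, A, S, "participation")
        self.schooling = _as3d(self.schooling, T, A, S, "schooling")
        self.yll = _as2d(self.yll, T, A, "yll")
        self.yld = _as2d(self.yld, T, A, "yld")
        self.prevalence = _as2d(self.prevalence, T, A, "prevalence")
        self.gdp = _as1d(self.gdp, T, "gdp")
        self.saving_rate = _as1d(self.saving_rate, T, "saving_rate")
        self.treatment_cost = _as1d(self.treatment_cost, T, "treatment_cost")
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if len(self.years) < 2:
            raise ValidationError("year grid must span at least 2 years")
        if np.any(np.diff(self.years) != 1):
            raise ValidationError("year grid must be contiguous")
        if len(self.ages) < 3:
            raise ValidationError("age grid must have at least 3 groups")
        sig, sig_r = self.all_cause_mortality, self.diabetes_mortality
        if np.any(sig < 0) or np.any(sig >= 1):
            raise ValidationError("all_cause_mortality must lie in [0, 1)")
        if np.any(sig_r < 0) or np.any(sig_r - sig > 1e-12):
            raise ValidationError("diabetes_mortality must satisfy 0 <= sigma_r <= sigma")
        if np.any(self.participation < 0) or np.any(self.participation > 1):
            raise ValidationError("participation must lie in [0, 1]")
        for nm in ("population", "yll", "yld", "prevalence", "gdp", "treatment_cost"):
            if np.any(getattr(self, nm) < 0):
                raise ValidationError(f"{nm} must be nonnegative")
        pop_by_age = self.population.sum(axis=2)
        if np.any(self.prevalence - pop_by_age > 1e-6 * np.maximum(pop_by_age, 1.0)):
            raise ValidationError("prevalence cannot exceed population in any year/age cell")
        if self.capital0 < 0:
            raise ValidationError("capital0 must be nonnegative")
        if not 0 <= self.alpha <= 1:
            raise ValidationError("alpha must lie in [0, 1]")
        if not 0 <= self.delta <= 1:
            raise ValidationError("delta must lie in [0, 1]")
        if self.caregiver_weights is not None:
            w = np.asarray(self.caregiver_weights, dtype=float)
            if w.shape != (len(self.ages),):
                raise ShapeError("caregiver_weights must be a per-age vector")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValidationError("caregiver_weights must sum to 1")
            self.caregiver_weights = w

    # -- helpers ---------------------------------------------------------
    @property
    def n_years(self) -> int:
        return len(self.years)

    def population_grid(self) -> CohortGrid:
        return CohortGrid(self.population, "status_quo")

    def replace(self, **kwargs) -> "CountryInput":
        """Return a copy with some fields replaced (re-validated)."""
        return replace(self, **kwargs)
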