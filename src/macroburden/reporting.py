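"""Aggregation, imputation and report tables.

Country-level burdens are aggregated to World Bank regions and income
groups by summing totals, GDP and population first and computing ratios
(percent of GDP, per-capita loss) from the group sums — never by averaging
country ratios. Countries with incomplete input data are imputed from an
OLS regression of log per-capita burden on log GDP per capita and the
disease DALY rate, fitted on the complete countries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DomainError, ValidationError

__all__ = [
    "percent_of_gdp",
    "per_capita",
    "GroupingMap",
    "aggregate",
    "ImputationModel",
    "fit_imputation",
    "impute",
    "write_report",
]

logger = logging.getLogger(__name__)

#: World Bank region strata (plus the residual stratum for territories
#: outside the seven regions).
REGIONS = (
    "East Asia and Pacific",
    "Europe and Central Asia",
    "Latin America and Caribbean",
    "Middle East and North Africa",
    "North America",
    "South Asia",
    "Sub-Saharan Africa",
    "Others",
)

INCOME_GROUPS = (
    "Low income",
    "Lower-middle income",
    "Upper-middle income",
    "High income",
)


def percent_of_gdp(total_burden: float, gdp_by_year) -> float:
    """Burden as a percentage of the GDP sum over the horizon."""
    gdp = np.asarray(gdp_by_year, dtype=float)
    denom = gdp.sum()
    if denom <= 0:
        raise DomainError("GDP sum over the horizon must be positive")
    return 100.0 * total_burden / denom


def per_capita(total_burden: float, pop_by_year) -> float:
    """Burden per person, against the annual-average population."""
    pop = np.asarray(pop_by_year, dtype=float)
    denom = pop.mean()
    if denom <= 0:
        raise DomainError("average population must be positive")
    return total_burden / denom


@dataclass
class GroupingMap:
    """Country -> region / income-group assignment.

    ``table`` needs columns ``country``, ``region``, ``income``; each
    country must appear exactly once.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"country", "region", "income"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"grouping map missing columns: {sorted(missing)}")
        dup = self.table["country"][self.table["country"].duplicated()]
        if len(dup):
            raise ValidationError(f"countries mapped more than once: {sorted(dup)}")

    def lookup(self, countries) -> pd.DataFrame:
        m = self.table.set_index("country")
        unmapped = [c for c in countries if c not in m.index]
        if unmapped:
            raise ValidationError(f"unmapped countries: {sorted(unmapped)}")
        return m.loc[list(countries)].reset_index()


def _group_rows(df: pd.DataFrame, key: str) -> pd.DataFrame:
    num_cols = [c for c in ("total", "total_low", "total_high") if c in df.columns]
    g = df.groupby(key, sort=False)[num_cols + ["gdp_sum", "pop_mean"]].sum()
    out = g.reset_index().rename(columns={key: "group"})
    out.insert(0, "stratum", key)
    for c in num_cols:
        suffix = c.removeprefix("total")
        out[f"pct_gdp{suffix}"] = 100.0 * out[c] / out["gdp_sum"]
        out[f"per_capita{suffix}"] = out[c] / out["pop_mean"]
    return out


def aggregate(results: pd.DataFrame, mapping: GroupingMap) -> pd.DataFrame:
    """Stratified burden table by region and income group, plus the total.

    ``results`` needs one row per country with columns ``country``,
    ``total`` (discounted burden), ``gdp_sum`` (undiscounted GDP summed
    over the horizon) and ``pop_mean`` (annual-average population);
    optional ``total_low``/``total_high`` bound columns are carried
    through. Group percent-of-GDP and per-capita figures are computed from
    the group sums.
    """
    labels = mapping.lookup(results["country"])
    df = results.merge(labels, on="country", validate="one_to_one")
    parts = [_group_rows(df, "region"), _group_rows(df, "income")]
    world = df.assign(world="Total")
    parts.append(_group_rows(world, "world"))
    return pd.concat(parts, ignore_index=True)


@dataclass
class ImputationModel:
    """Fitted linear imputation model for countries with incomplete data."""

    result: sm.regression.linear_model.RegressionResultsWrapper
    covariates: tuple[str, ...]
    n: int

    @property
    def r_squared(self) -> float:
        return float(self.result.rsquared)

    @property
    def params(self) -> pd.Series:
        return self.result.params


def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    if np.any(df["gdp_per_capita"] <= 0):
        raise DomainError("gdp_per_capita must be positive (log transform)")
    X = pd.DataFrame(index=df.index)
    for cov in covariates:
        if cov == "log_gdp_per_capita":
            X[cov] = np.log(df["gdp_per_capita"])
        elif cov in df.columns:
            X[cov] = df[cov]
        else:
            raise ValidationError(f"missing covariate column: {cov}")
    return sm.add_constant(X, has_constant="add")


def fit_imputation(
    complete: pd.DataFrame,
    covariates=("log_gdp_per_capita", "daly_rate"),
) -> ImputationModel:
    """OLS of log per-capita burden on the covariates, complete countries only.

    ``complete`` needs columns ``per_capita_burden`` (> 0),
    ``gdp_per_capita`` (> 0) and any further covariates (default: the
    disease DALY rate). Requires at least 10 complete countries and a
    full-rank design.
    """
    if len(complete) < 10:
        raise ValidationError(
            f"imputation needs >= 10 complete countries; got {len(complete)}"
        )
    if np.any(complete["per_capita_burden"] <= 0):
        raise DomainError("per-capita burden must be positive to fit on the log scale")
    X = _design(complete, covariates)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValidationError(f"rank-deficient design; near-collinear covariates: {worst}")
    y = np.log(complete["per_capita_burden"].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    return ImputationModel(result=res, covariates=tuple(covariates), n=len(complete))


def impute(model: ImputationModel, incomplete: pd.DataFrame) -> pd.DataFrame:
    """Predict per-country burdens for incomplete countries.

    Returns a frame with ``country``, ``per_capita_burden`` (clamped
    nonnegative), ``total`` (scaled by ``pop_mean`` when present) and an
    ``imputed`` flag.
    """
    X = _design(incomplete, model.covariates)
    pred = np.maximum(np.exp(model.result.predict(X)), 0.0)
    out = pd.DataFrame({
        "country": incomplete["country"].to_numpy(),
        "per_capita_burden": pred,
        "imputed": True,
    })
    if "pop_mean" in incomplete.columns:
        out["total"] = pred * incomplete["pop_mean"].to_numpy(dtype=float)
    return out


def _display_round(df: pd.DataFrame) -> pd.DataFrame:
    """Display variant matching the reporting precision: integer INT$,
    3-decimal percentages."""
    disp = df.copy()
    if disp.empty:
        return disp
    for c in disp.columns:
        if c.startswith(("total", "per_capita")) or c in ("gdp_sum", "pop_mean"):
            disp[c] = disp[c].round(0).astype("Int64", errors="ignore")
        elif c.startswith("pct_gdp"):
            disp[c] = disp[c].map(lambda v: f"{v:.3f}")
    return disp


def write_report(tables: dict[str, pd.DataFrame], path) -> list[Path]:
    """Write each table as ``<name>.csv`` plus ``<name>_display.csv``.

    The raw files keep full precision; the display variants round money to
    integers and percentages to 3 decimals.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = path / f"{name}.csv"
        df.to_csv(p, index=False)
        pd_ = path / f"{name}_display.csv"
        _display_round(df).to_csv(pd_, index=False)
        written.extend([p, pd_])
    return written
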