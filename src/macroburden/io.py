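"""Panel CSV / YAML round-trip.

The on-disk dialect is a long-format CSV with columns
``country, year, age, sex, variable, value`` (UTF-8, header row, '.'
decimal) holding every gridded series, plus a YAML block for the country
scalars (alpha, delta, eta1-eta3, K0). Year-only series use empty age/sex
fields; year-age series use an empty sex field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .panel import CountryInput

__all__ = ["write_country", "read_country"]

_GRID3 = ("population", "all_cause_mortality", "diabetes_mortality",
          "participation", "schooling")
_GRID2 = ("yll", "yld", "prevalence")
_SERIES = ("gdp", "saving_rate", "treatment_cost")
_SCALARS = ("alpha", "delta", "eta1", "eta2", "eta3", "capital0")


def write_country(inp: CountryInput, csv_path, yaml_path) -> None:
    """Write one country panel to the long CSV plus a YAML scalar block."""
    frames = []
    T, A = inp.n_years, len(inp.ages)
    yy, aa, ss = np.meshgrid(inp.years, inp.ages, np.arange(len(inp.sexes)), indexing="ij")
    sex_labels = np.asarray(inp.sexes)
    for var in _GRID3:
        frames.append(pd.DataFrame({
            "year": yy.ravel(), "age": aa.ravel(), "sex": sex_labels[ss.ravel()],
            "variable": var, "value": getattr(inp, var).ravel(),
        }))
    y2, a2 = np.meshgrid(inp.years, inp.ages, indexing="ij")
    for var in _GRID2:
        frames.append(pd.DataFrame({
            "year": y2.ravel(), "age": a2.ravel(), "sex": "",
            "variable": var, "value": getattr(inp, var).ravel(),
        }))
    for var in _SERIES:
        frames.append(pd.DataFrame({
            "year": inp.years, "age": "", "sex": "",
            "variable": var, "value": getattr(inp, var),
        }))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "country", inp.name)
    df.to_csv(csv_path, index=False)

    scalars = {k: float(getattr(inp, k)) for k in _SCALARS}
    scalars["country"] = inp.name
    scalars["sexes"] = list(inp.sexes)
    if inp.caregiver_weights is not None:
        scalars["caregiver_weights"] = [float(v) for v in inp.caregiver_weights]
    Path(yaml_path).write_text(yaml.safe_dump(scalars, sort_keys=True))


def read_country(csv_path, yaml_path) -> CountryInput:
    """Read a country panel written by :func:`write_country`."""
    df = pd.read_csv(csv_path, keep_default_na=False)
    scalars = yaml.safe_load(Path(yaml_path).read_text())
    missing = set(_GRID3 + _GRID2 + _SERIES) - set(df["variable"].unique())
    if missing:
        raise ValidationError(f"panel CSV missing variables: {sorted(missing)}")

    df["year"] = df["year"].astype(int)
    grid_rows = df["variable"].isin(_GRID3 + _GRID2)
    df.loc[grid_rows, "age"] = df.loc[grid_rows, "age"].astype(int)
    years = np.sort(df.loc[df["variable"] == "gdp", "year"].unique())
    pop = df[df["variable"] == "population"]
    ages = np.sort(pop["age"].unique()).astype(int)
    sexes = list(scalars["sexes"])
    T, A, S = len(years), len(ages), len(sexes)

    kwargs = {}
    for var in _GRID3:
        sub = df[df["variable"] == var]
        piv = sub.pivot_table(index="year", columns=["age", "sex"], values="value")
        arr = np.empty((T, A, S))
        for j, a in enumerate(ages):
            for k, s in enumerate(sexes):
                arr[:, j, k] = piv[(a, s)].loc[years].to_numpy()
        kwargs[var] = arr
    for var in _GRID2:
        sub = df[df["variable"] == var]
        piv = sub.pivot_table(index="year", columns="age", values="value")
        kwargs[var] = piv.loc[years, ages].to_numpy()
    for var in _SERIES:
        sub = df[df["variable"] == var].set_index("year")["value"]
        kwargs[var] = sub.loc[years].to_numpy(dtype=float)

    cw = scalars.get("caregiver_weights")
    return CountryInput(
        name=str(scalars.get("country", df["country"].iloc[0])),
        years=years, ages=ages, sexes=sexes,
        capital0=float(scalars["capital0"]),
        alpha=float(scalars["alpha"]), delta=float(scalars["delta"]),
        eta1=float(scalars["eta1"]), eta2=float(scalars["eta2"]),
        eta3=float(scalars["eta3"]),
        caregiver_weights=None if cw is None else np.asarray(cw, dtype=float),
        **kwargs,
    )
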