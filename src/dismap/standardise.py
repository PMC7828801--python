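"""Indirect age–gender standardisation, SMR estimation and crude rates.

Internal (indirect) standardisation: province-wide stratum risks
``risk_j = deaths_j / population_j`` over the 40 gender × age strata are
applied to each area's population, ``e_i = Σ_j pop_ij · risk_j``.  By
construction the expected counts conserve the observed total per year,
``Σ_i e_i = Σ_i y_i``.  The SMR is the Poisson maximum-likelihood estimate
``y/e`` with exact (Garwood, chi-square based) 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import StudyBundle


@dataclass
class SmrEstimate:
    """SMR maximum-likelihood estimate with an exact Poisson 95% interval."""

    y: int
    e: float
    smr: float
    ci_low: float
    ci_high: float
    rate_per_1000: float | None = None


def compute_stratum_risks(
    population: pd.DataFrame,
    deaths_strata: pd.DataFrame,
    year_mode: str = "per-year",
) -> pd.DataFrame:
    """Province-wide death risk per gender × age stratum.

    ``per-year`` re-estimates the risks each year against that year's
    (reference) population; ``pooled`` uses deaths and person-years summed
    over the whole study window.  Returns columns
    ``year`` (absent when pooled), ``gender``, ``age_class``, ``risk``.
    """
    pop_strat = population.groupby(["year", "gender", "age_class"], as_index=False)[
        "count"
    ].sum()
    d = deaths_strata.groupby(["year", "gender", "age_class"], as_index=False)[
        "deaths"
    ].sum()
    if year_mode == "per-year":
        m = pop_strat.merge(d, on=["year", "gender", "age_class"], how="left")
        m["deaths"] = m["deaths"].fillna(0.0)
        bad = (m["deaths"] > 0) & (m["count"] <= 0)
        if bad.any():
            raise ValueError("stratum with deaths but zero population")
        m["risk"] = np.where(m["count"] > 0, m["deaths"] / m["count"], 0.0)
        return m[["year", "gender", "age_class", "risk"]]
    if year_mode == "pooled":
        pp = pop_strat.groupby(["gender", "age_class"], as_index=False)["count"].sum()
        dd = d.groupby(["gender", "age_class"], as_index=False)["deaths"].sum()
        m = pp.merge(dd, on=["gender", "age_class"], how="left")
        m["deaths"] = m["deaths"].fillna(0.0)
        bad = (m["deaths"] > 0) & (m["count"] <= 0)
        if bad.any():
            raise ValueError("stratum with deaths but zero population")
        m["risk"] = np.where(m["count"] > 0, m["deaths"] / m["count"], 0.0)
        return m[["gender", "age_class", "risk"]]
    raise ValueError("year_mode must be 'per-year' or 'pooled'")


def compute_expected_counts(
    population: pd.DataFrame,
    deaths_strata: pd.DataFrame,
    year_mode: str = "per-year",
) -> pd.DataFrame:
    """Expected deaths per area-year from internal standardisation.

    Returns columns ``area_id``, ``year``, ``e``.
    """
    risks = compute_stratum_risks(population, deaths_strata, year_mode)
    keys = ["gender", "age_class"] if year_mode == "pooled" else ["year", "gender", "age_class"]
    m = population.merge(risks, on=keys, how="left")
    m["risk"] = m["risk"].fillna(0.0)
    m["e_part"] = m["count"] * m["risk"]
    out = m.groupby(["area_id", "year"], as_index=False)["e_part"].sum()
    return out.rename(columns={"e_part": "e"}).sort_values(
        ["area_id", "year"], ignore_index=True
    )


def compute_smr(y: int, e: float, population: int | None = None) -> SmrEstimate:
    """SMR = y/e with the exact Poisson (chi-square) 95% interval.

    ``ci_low = χ²(0.025, 2y)/(2e)`` (0 when y = 0) and
    ``ci_high = χ²(0.975, 2y+2)/(2e)``.
    """
    if e <= 0:
        raise ValueError("expected count must be positive")
    y = int(y)
    if y < 0:
        raise ValueError("observed count must be nonnegative")
    smr = y / e
    lo = 0.0 if y == 0 else stats.chi2.ppf(0.025, 2 * y) / (2 * e)
    hi = stats.chi2.ppf(0.975, 2 * y + 2) / (2 * e)
    rate = None if population is None else y / population * 1000.0
    return SmrEstimate(y=y, e=float(e), smr=smr, ci_low=float(lo), ci_high=float(hi),
                       rate_per_1000=rate)


def smr_table(bundle: StudyBundle, year_mode: str = "per-year") -> pd.DataFrame:
    """Per area-year observed/expected deaths, SMR and exact 95% interval."""
    if bundle.deaths is None or bundle.deaths_strata is None:
        raise ValueError("bundle carries no death tables")
    expected = compute_expected_counts(bundle.population, bundle.deaths_strata, year_mode)
    m = expected.merge(bundle.deaths, on=["area_id", "year"], how="left", validate="1:1")
    if m["deaths"].isna().any():
        raise ValueError("deaths table missing area-year rows")
    pop = bundle.population_totals()
    m = m.merge(pop, on=["area_id", "year"])
    rows = []
    for r in m.itertuples(index=False):
        est = compute_smr(r.deaths, r.e, population=r.population)
        rows.append(
            (r.area_id, r.year, est.y, est.e, est.smr, est.ci_low, est.ci_high,
             est.rate_per_1000)
        )
    return pd.DataFrame(
        rows,
        columns=["area_id", "year", "y", "e", "smr", "ci_low", "ci_high",
                 "rate_per_1000"],
    ).sort_values(["area_id", "year"], ignore_index=True)


def check_conservation(table: pd.DataFrame, tol: float = 1e-9) -> None:
    """Assert Σe = Σy per year (internal standardisation conserves totals)."""
    g = table.groupby("year")[["y", "e"]].sum()
    if not np.allclose(g["y"], g["e"], atol=tol, rtol=0):
        raise AssertionError(f"standardisation does not conserve totals:\n{g}")


def compute_crude_rates(
    deaths_by_gender: pd.DataFrame,
    population_by_gender: dict[str, int],
    decimals: int = 2,
) -> pd.DataFrame:
    """Crude mortality rates per 1000 by gender and overall, per year.

    ``deaths_by_gender`` has columns ``year``, ``M``, ``F``; the reference
    population is fixed across years.  Rates are rounded to ``decimals`` for
    reporting; raw (full-precision) columns are retained alongside.
    """
    pm, pf = population_by_gender["M"], population_by_gender["F"]
    if pm <= 0 or pf <= 0:
        raise ValueError("populations must be positive")
    out = deaths_by_gender.copy()
    out["total"] = out["M"] + out["F"]
    out["rate_m_raw"] = out["M"] / pm * 1000.0
    out["rate_f_raw"] = out["F"] / pf * 1000.0
    out["rate_total_raw"] = out["total"] / (pm + pf) * 1000.0
    for c in ("m", "f", "total"):
        out[f"rate_{c}"] = out[f"rate_{c}_raw"].round(decimals)
    return out
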