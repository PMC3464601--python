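"""Accuracy, comparison and rate computations.

Compares each unlinked case-selection scenario against the reference
standard at episode level (sensitivity, specificity, PPV, NPV with 95% CIs,
plus overestimation), tests prevalence differences between data sources,
and computes age-specific and directly age-standardised admission rates
per 100,000 community-dwelling population.

True negatives are defined over extracted fall-injury episodes: an episode
not labelled an incident case by the reference standard and not selected by
the scenario.  This is the single largest analytic judgement call in the
module (administrative datasets have no natural "non-case" unit) and is
documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ._util import DEFAULT_AGE_BANDS, round_half_up

_CI_METHODS = {"wilson": "wilson", "exact": "beta", "wald": "normal"}


def proportion_ci(
    x: int, n: int, method: str = "wilson", alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided CI for a binomial proportion, as fractions in [0,1]."""
    if method not in _CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}; use wilson|exact|wald")
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(x, n, alpha=alpha, method=_CI_METHODS[method])
    # guard the point estimate against floating-point wobble at the edges
    return (
        float(np.clip(min(lo, x / n), 0, 1)),
        float(np.clip(max(hi, x / n), 0, 1)),
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_reference(self) -> int:
        return self.tp + self.fn

    @property
    def n_scenario(self) -> int:
        return self.tp + self.fp


def confusion(ref_labels: pd.Series, scenario_labels: pd.Series) -> ConfusionMatrix:
    """Cross-classify episodes by reference label x scenario label.

    Both Series must be boolean and indexed by the same episode ids.
    """
    if not ref_labels.index.equals(scenario_labels.index):
        diff = ref_labels.index.symmetric_difference(scenario_labels.index)
        raise ValueError(
            f"label vectors cover different episode sets ({len(diff)} episodes differ)"
        )
    r = ref_labels.astype(bool).to_numpy()
    s = scenario_labels.astype(bool).to_numpy()
    return ConfusionMatrix(
        tp=int((r & s).sum()),
        fp=int((~r & s).sum()),
        fn=int((r & ~s).sum()),
        tn=int((~r & ~s).sum()),
    )


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy of one scenario against the reference standard (percent)."""

    scenario: str
    n_reference: int
    n_scenario: int
    overestimation_pct: float
    sensitivity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity: float | None
    specificity_ci: tuple[float, float] | None
    ppv: float | None
    ppv_ci: tuple[float, float] | None
    npv: float | None
    npv_ci: tuple[float, float] | None


def overestimation(n_scenario: int, n_reference: int) -> float:
    """Multiple-counting bias (%) of a scenario count over the reference
    count, rounded to one decimal (half up)."""
    if n_reference <= 0:
        raise ValueError("reference count must be positive")
    return round_half_up(100 * (n_scenario - n_reference) / n_reference, 1)


def accuracy_measures(
    cm: ConfusionMatrix,
    n_reference: int | None = None,
    n_scenario: int | None = None,
    scenario: str = "",
    ci_method: str = "wilson",
) -> AccuracyReport:
    """Sensitivity, specificity, PPV, NPV (with 95% CIs) and overestimation.

    Counts default to the confusion-matrix marginals; zero-denominator
    measures are reported as None.
    """
    n_ref = cm.n_reference if n_reference is None else n_reference
    n_scen = cm.n_scenario if n_scenario is None else n_scenario

    def measure(x: int, n: int):
        if n == 0:
            return None, None
        lo, hi = proportion_ci(x, n, method=ci_method)
        return 100 * x / n, (100 * lo, 100 * hi)

    sens, sens_ci = measure(cm.tp, cm.tp + cm.fn)
    spec, spec_ci = measure(cm.tn, cm.tn + cm.fp)
    ppv, ppv_ci = measure(cm.tp, cm.tp + cm.fp)
    npv, npv_ci = measure(cm.tn, cm.tn + cm.fn)
    return AccuracyReport(
        scenario=scenario,
        n_reference=n_ref,
        n_scenario=n_scen,
        overestimation_pct=overestimation(n_scen, n_ref),
        sensitivity=sens, sensitivity_ci=sens_ci,
        specificity=spec, specificity_ci=spec_ci,
        ppv=ppv, ppv_ci=ppv_ci,
        npv=npv, npv_ci=npv_ci,
    )


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> dict:
    """Two-sample test of proportions: chi-square without continuity
    correction, or Fisher's exact test when any expected cell is below 5.
    Two-tailed."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return {"statistic": None, "p_value": float(p), "method": "fisher_exact"}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"statistic": float(chi2), "p_value": float(p), "method": "chi_square"}


def age_specific_rates(
    incidents: pd.DataFrame, population: pd.DataFrame
) -> pd.DataFrame:
    """Admission rates per 100,000 community-dwelling population by
    (fiscal_year, sex, age_band).

    ``incidents`` needs fiscal_year, sex and age_band columns; every
    stratum with cases must have a population row.
    """
    cases = (
        incidents.groupby(["fiscal_year", "sex", "age_band"], observed=True)
        .size()
        .rename("cases")
        .reset_index()
    )
    merged = population.merge(cases, on=["fiscal_year", "sex", "age_band"], how="outer")
    missing = merged[merged["community_denominator"].isna() & merged["cases"].notna()]
    if len(missing):
        strata = missing[["fiscal_year", "sex", "age_band"]].to_dict("records")
        raise ValueError(f"no population row for strata: {strata}")
    merged["cases"] = merged["cases"].fillna(0).astype(int)
    merged["rate_per_100k"] = (
        100_000 * merged["cases"] / merged["community_denominator"]
    )
    return merged.sort_values(["fiscal_year", "sex", "age_band"]).reset_index(drop=True)


def standard_population(
    population: pd.DataFrame, bands: tuple[str, ...] = DEFAULT_AGE_BANDS
) -> pd.DataFrame:
    """Build a standard population (age_band, weight) from a population
    table by pooling years and sexes; weights sum to 1."""
    pooled = (
        population.groupby("age_band", observed=True)["population_estimate"]
        .sum()
        .reindex(list(bands))
    )
    total = pooled.sum()
    return pd.DataFrame(
        {"age_band": pooled.index, "weight": (pooled / total).to_numpy()}
    )


def direct_standardise(
    rate_table: pd.DataFrame, standard: pd.DataFrame
) -> pd.DataFrame:
    """Directly age-standardised rate per fiscal year.

    Age-specific rates are first pooled over sex within (year, band) —
    summed cases over summed denominators — then weighted by the standard
    population's age structure.
    """
    std = standard.copy()
    if "weight" not in std.columns:
        std["weight"] = std["population_estimate"] / std["population_estimate"].sum()
    std["weight"] = std["weight"] / std["weight"].sum()

    pooled = (
        rate_table.groupby(["fiscal_year", "age_band"], observed=True)[
            ["cases", "community_denominator"]
        ]
        .sum()
        .reset_index()
    )
    pooled["rate_per_100k"] = (
        100_000 * pooled["cases"] / pooled["community_denominator"]
    )
    rows = []
    for year, grp in pooled.groupby("fiscal_year"):
        merged = std.merge(grp, on="age_band", how="left")
        if merged["rate_per_100k"].isna().any():
            missing = merged.loc[merged["rate_per_100k"].isna(), "age_band"].tolist()
            raise ValueError(f"rate table missing age bands {missing} for {year}")
        rows.append(
            dict(
                fiscal_year=year,
                standardised_rate_per_100k=float(
                    (merged["weight"] * merged["rate_per_100k"]).sum()
                ),
            )
        )
    return pd.DataFrame(rows)
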