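"""Force of infection from mean patient age and the catalytic model.

For an agent causing acute illness with lifelong immunity at endemic
equilibrium, the force of infection λ (per susceptible per year) is well
approximated by the inverse of the mean patient age A.  The catalytic model
then tracks the fraction V(t) of a birth cohort still naive at age t:

    dV/dt = -λ V,  V(0) = 1   ⇒   V(t) = exp(-t / A)

Combining 1 - V(t) with the cumulative risk of an actual diagnosis by age t
(average annual cases under age t over the average annual birth cohort)
yields the probability that an infection manifests clinically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "foi_from_mean_age",
    "susceptible_fraction",
    "cumulative_diagnosis_risk",
    "manifestation_probability",
    "CatalyticResult",
    "catalytic_report",
]


def foi_from_mean_age(mean_age: float) -> float:
    """λ = 1/A: the force of infection implied by the mean patient age (1/year)."""
    if mean_age <= 0:
        raise ValueError(f"mean patient age must be positive, got {mean_age}")
    return 1.0 / mean_age


def susceptible_fraction(mean_age: float, t) -> float | np.ndarray:
    """V(t) = exp(-t/A): fraction of a cohort still naive at age t years."""
    if mean_age <= 0:
        raise ValueError(f"mean patient age must be positive, got {mean_age}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("age t must be non-negative")
    v = np.exp(-t_arr / mean_age)
    return float(v) if np.isscalar(t) else v


def cumulative_diagnosis_risk(
    annual_cases_under_t: float,
    annual_births: float,
    annual_deaths_under_t: float | None = None,
) -> float:
    """Fraction of a birth cohort diagnosed by age t.

    Ratio of the average annual case count in the age band [0, t) to the
    average annual birth cohort.  The default leaves the denominator
    uncorrected for child mortality; passing ``annual_deaths_under_t``
    subtracts it (survival-corrected variant; negligible where child
    mortality is very low).
    """
    if annual_births <= 0:
        raise ValueError("annual births must be positive")
    if annual_cases_under_t < 0:
        raise ValueError("annual case count must be non-negative")
    denom = annual_births
    if annual_deaths_under_t is not None:
        denom -= annual_deaths_under_t
        if denom <= 0:
            raise ValueError("death correction exceeds the birth cohort")
    return annual_cases_under_t / denom


def manifestation_probability(diagnosis_risk: float, infected_fraction: float) -> float:
    """P(clinical disease | infection) = diagnosis risk / infected fraction."""
    if not (0 < infected_fraction <= 1):
        raise ValueError("infected fraction must lie in (0, 1]")
    if diagnosis_risk < 0:
        raise ValueError("diagnosis risk must be non-negative")
    return diagnosis_risk / infected_fraction


@dataclass
class CatalyticResult:
    """Full catalytic-model chain for one disease."""

    mean_age: float
    foi: float
    ages: tuple[float, ...]
    susceptible: tuple[float, ...]
    infected: tuple[float, ...]
    diagnosis_risk: dict = field(default_factory=dict)
    manifestation: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "mean_age_years": self.mean_age,
            "foi_per_year": self.foi,
            "by_age": {
                f"{t:g}": {
                    "susceptible_fraction": v,
                    "infected_fraction": inf,
                    "infected_percent_rounded": round(100 * inf),
                }
                for t, v, inf in zip(self.ages, self.susceptible, self.infected)
            },
        }
        if self.diagnosis_risk:
            out["diagnosis_risk"] = {
                k: {"raw": v, "percent_rounded_1dp": round(100 * v, 1)}
                for k, v in self.diagnosis_risk.items()
            }
        if self.manifestation:
            out["manifestation_probability"] = {
                k: {"raw": v, "percent_rounded": round(100 * v)}
                for k, v in self.manifestation.items()
            }
        return out


def catalytic_report(
    mean_age: float,
    ages=(3.0, 5.0),
    annual_cases_by_age: dict | None = None,
    annual_births: float | None = None,
    annual_deaths: float | None = None,
) -> CatalyticResult:
    """Run the catalytic chain: FOI, V(t), diagnosis risk, manifestation probability.

    ``annual_cases_by_age`` maps an age t (years) to the average annual number
    of cases in [0, t); with ``annual_births`` it yields the cumulative
    diagnosis risk by t and, divided by 1 - V(t), the manifestation
    probability.
    """
    lam = foi_from_mean_age(mean_age)
    v = [susceptible_fraction(mean_age, t) for t in ages]
    infected = [1.0 - x for x in v]
    result = CatalyticResult(
        mean_age=mean_age,
        foi=lam,
        ages=tuple(float(a) for a in ages),
        susceptible=tuple(v),
        infected=tuple(infected),
    )
    if annual_cases_by_age and annual_births:
        for t, cases in annual_cases_by_age.items():
            risk = cumulative_diagnosis_risk(cases, annual_births, annual_deaths)
            result.diagnosis_risk[f"{float(t):g}"] = risk
            vt = susceptible_fraction(mean_age, float(t))
            result.manifestation[f"{float(t):g}"] = manifestation_probability(
                risk, 1.0 - vt
            )
    return result
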