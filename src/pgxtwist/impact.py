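"""Translate a per-year GMTE into population-impact quantities.

A per-year additive hazard excess, multiplied by the number of carrier
patient-years observed on treatment, gives the number of diagnoses that
could have been avoided had carriers experienced the noncarrier treatment
effect; dividing by the total number of diagnoses among treated patients
gives the percent reduction in incidence.  Both maps are linear, so
confidence-interval endpoints transform identically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError


@dataclass
class ImpactEstimate:
    """Avoidable-diagnosis count and percent reduction with CIs."""

    gmte_per_year: float
    carrier_patient_years: float
    total_events_treated: int
    avoided_count: float
    avoided_ci: tuple[float, float]
    percent_reduction: float
    percent_ci: tuple[float, float]

    def __str__(self) -> str:
        lo, hi = self.avoided_ci
        plo, phi = self.percent_ci
        return (
            f"{self.avoided_count:.0f} diagnoses avoidable "
            f"(95% CI {lo:.0f} to {hi:.0f}); incidence reduction "
            f"{self.percent_reduction:.1f}% (95% CI {plo:.1f} to {phi:.1f})"
        )


def ci_from_p(estimate: float, p: float) -> tuple[float, tuple[float, float]]:
    """Back-calculate (se, Wald 95% CI) from an estimate and two-sided p.

    Used to audit printed confidence intervals from printed estimate/p pairs.
    p values extremely close to 1 give unbounded intervals and are rejected.
    """
    if not 0.0 < p < 1.0:
        raise ConfigError("p must lie strictly inside (0, 1)")
    if estimate == 0:
        raise ConfigError("cannot back-calculate an SE from a zero estimate")
    z = stats.norm.isf(p / 2.0)
    if p > 0.999 or z <= 0:
        raise ConfigError(f"p = {p} too close to 1: CI width unbounded")
    se = abs(estimate) / z
    half = 1.959963984540054 * se
    return se, (estimate - half, estimate + half)


def avoidable_count(
    gmte_per_year: float,
    patient_years: float,
    ci: tuple[float, float] | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Avoidable diagnoses = GMTE x carrier patient-years (CI scaled alike)."""
    if patient_years <= 0:
        raise ConfigError("patient_years must be positive")
    count = gmte_per_year * patient_years
    if ci is None:
        return count, None
    lo, hi = sorted((ci[0] * patient_years, ci[1] * patient_years))
    return count, (lo, hi)


def percent_reduction(
    avoided: float,
    total_events: float,
    ci: tuple[float, float] | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Percent of treated diagnoses avoidable: 100 x avoided / total."""
    if total_events <= 0:
        raise ConfigError("total_events must be positive")
    pct = 100.0 * avoided / total_events
    if ci is None:
        return pct, None
    lo, hi = sorted((100.0 * ci[0] / total_events, 100.0 * ci[1] / total_events))
    return pct, (lo, hi)


def impact_estimate(
    gmte_per_year: float,
    patient_years: float,
    total_events: int,
    *,
    se: float | None = None,
    p: float | None = None,
) -> ImpactEstimate:
    """Full impact translation from a GMTE and its uncertainty.

    Uncertainty may be given as a standard error or as a two-sided p-value
    (from which the SE is back-calculated).
    """
    if se is None:
        if p is None:
            raise ConfigError("provide either se or p for the GMTE")
        se, _ = ci_from_p(gmte_per_year, p)
    half = 1.959963984540054 * se
    gmte_ci = (gmte_per_year - half, gmte_per_year + half)
    count, count_ci = avoidable_count(gmte_per_year, patient_years, gmte_ci)
    pct, pct_ci = percent_reduction(count, total_events, count_ci)
    return ImpactEstimate(
        gmte_per_year=gmte_per_year,
        carrier_patient_years=patient_years,
        total_events_treated=int(total_events),
        avoided_count=count,
        avoided_ci=count_ci,
        percent_reduction=pct,
        percent_ci=pct_ci,
    )
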