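"""Cumulative incidence, censored person-time rates, and exact intervals.

Cumulative incidence is cases divided by patients evaluated, with exact
(Clopper-Pearson) binomial confidence limits; zero-case cells carry the
exact one-sided 97.5% upper bound 100*(1 - 0.025^(1/n)).  Incidence
rates per 100 person-years divide cases by exposed person-time summed
across a patient's treatment episodes and censored at the first
qualifying elevation; rate limits come from exact Poisson (chi-square)
bounds on the case count.  All percentages and rates are reported rounded
half-up to one decimal, matching conventional table formatting.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .cohort_exposure import Episode

__all__ = [
    "UNDEFINED",
    "IncidenceCell",
    "TimeToEventSummary",
    "round_half_up",
    "cumulative_incidence",
    "exact_binomial_ci",
    "zero_case_upper_bound",
    "person_time",
    "incidence_rate",
    "poisson_exact_ci",
    "time_to_event_summary",
    "build_incidence_table",
]

#: Marker for cells with an empty denominator (never rendered as zero).
UNDEFINED = "n/a"

STRATA = ("overall", "first_line", "second_line_plus")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), as printed tables round."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cumulative_incidence(n_cases: int, n_evaluated: int) -> float | str:
    """Percent of evaluated patients with the outcome, rounded to 1 decimal."""
    if n_evaluated == 0:
        return UNDEFINED
    if not 0 <= n_cases <= n_evaluated:
        raise ValueError("need 0 <= n_cases <= n_evaluated")
    return round_half_up(100.0 * n_cases / n_evaluated)


def exact_binomial_ci(
    n_cases: int, n_evaluated: int, level: float = 0.95
) -> tuple[float, float] | str:
    """Two-sided Clopper-Pearson interval, in percent, rounded to 1 decimal."""
    if n_evaluated == 0:
        return UNDEFINED
    if not 0 <= n_cases <= n_evaluated:
        raise ValueError("need 0 <= n_cases <= n_evaluated")
    alpha = 1.0 - level
    if n_cases == 0:
        lo = 0.0
    else:
        lo = stats.beta.ppf(alpha / 2, n_cases, n_evaluated - n_cases + 1)
    if n_cases == n_evaluated:
        hi = 1.0
    else:
        hi = stats.beta.ppf(1 - alpha / 2, n_cases + 1, n_evaluated - n_cases)
    return round_half_up(100.0 * lo), round_half_up(100.0 * hi)


def zero_case_upper_bound(n_evaluated: int) -> float | str:
    """Exact one-sided 97.5% upper bound (percent) for zero cases of n.

    Returned unrounded; table rendering rounds half-up to one decimal.
    """
    if n_evaluated == 0:
        return UNDEFINED
    return 100.0 * (1.0 - 0.025 ** (1.0 / n_evaluated))


def person_time(
    episodes: Sequence[Episode],
    event_date: datetime.date | None = None,
    year_length_days: float = 365.25,
) -> float:
    """Exposed person-years across episodes, censored at the event date.

    Day counts are inclusive of both endpoints and the event day is
    counted; episodes beginning after the event contribute nothing.
    """
    if event_date is not None and not any(ep.covers(event_date) for ep in episodes):
        raise ValueError(f"event date {event_date} falls outside all episodes")
    days = 0
    for ep in episodes:
        if event_date is None or ep.end <= event_date:
            days += ep.n_days
        elif ep.start <= event_date:
            days += (event_date - ep.start).days + 1
        # episodes starting after the event are censored away
    return days / year_length_days


def poisson_exact_ci(n_cases: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (chi-square) confidence bounds on a Poisson count."""
    alpha = 1.0 - level
    lo = 0.0 if n_cases == 0 else stats.chi2.ppf(alpha / 2, 2 * n_cases) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * n_cases + 2) / 2.0
    return lo, hi


def incidence_rate(
    n_cases: int, person_years: float, level: float = 0.95
) -> tuple[float, tuple[float, float]] | str:
    """Rate per 100 person-years with exact Poisson confidence limits."""
    if person_years <= 0:
        return UNDEFINED
    rate = 100.0 * n_cases / person_years
    lo, hi = poisson_exact_ci(n_cases, level)
    ci = (round_half_up(100.0 * lo / person_years), round_half_up(100.0 * hi / person_years))
    return round_half_up(rate), ci


@dataclass(frozen=True)
class TimeToEventSummary:
    drug: str
    category: str
    n_events: int
    mean_days: float
    median_days: float


def time_to_event_summary(
    days_to_event: Sequence[int], drug: str = "", category: str = ""
) -> TimeToEventSummary | None:
    """Mean and median days to event; None (rendered NA) for no events."""
    if not days_to_event:
        return None
    xs = sorted(days_to_event)
    n = len(xs)
    mean = sum(xs) / n
    median = float(xs[n // 2]) if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2.0
    return TimeToEventSummary(drug, category, n, round_half_up(mean), median)


@dataclass(frozen=True)
class IncidenceCell:
    """One cell of the incidence tables: a (drug, category, stratum) summary."""

    drug: str
    database: str
    category: str
    stratum: str
    n_cases: int
    n_evaluated: int
    person_years: float
    cum_inc_pct: float | str
    cum_inc_ci: tuple[float, float] | str
    rate_per_100py: float | str
    rate_ci: tuple[float, float] | str
    one_sided_zero_bound: bool = False


@dataclass(frozen=True)
class PatientCategoryRecord:
    """Per-(cohort entry, category) analysis input for the table builder."""

    patient_id: str
    drug: str
    category: str
    line_of_therapy: int
    eligible: bool
    event_days: int | None  # days from start to first qualifying elevation
    person_years: float  # censored at the event when present


def build_incidence_table(
    records: Iterable[PatientCategoryRecord],
    database: str,
    category_order: Sequence[str] | None = None,
) -> list[IncidenceCell]:
    """Aggregate per-patient category records into incidence cells.

    One cell per (drug, category, stratum) with strata overall /
    first-line / second-line-or-higher.  Ineligible patients (baseline
    already at or above the category's lower threshold) appear in neither
    numerator nor denominator; person-years are already censored at each
    patient's first event for the category.  Zero-case cells report the
    one-sided 97.5% upper bound in place of the two-sided interval.
    """
    groups: dict[tuple[str, str, str], list[PatientCategoryRecord]] = {}
    drugs: list[str] = []
    cats: list[str] = []
    for rec in records:
        if rec.drug not in drugs:
            drugs.append(rec.drug)
        if rec.category not in cats:
            cats.append(rec.category)
        strata = ["overall", "first_line" if rec.line_of_therapy == 1 else "second_line_plus"]
        for stratum in strata:
            groups.setdefault((rec.drug, rec.category, stratum), []).append(rec)
    if category_order is not None:
        cats = [c for c in category_order if c in cats]

    cells: list[IncidenceCell] = []
    for drug in drugs:
        for cat in cats:
            for stratum in STRATA:
                recs = [r for r in groups.get((drug, cat, stratum), []) if r.eligible]
                n_eval = len(recs)
                n_cases = sum(1 for r in recs if r.event_days is not None)
                py = sum(r.person_years for r in recs)
                zero = n_cases == 0 and n_eval > 0
                if zero:
                    ci: tuple[float, float] | str = (
                        0.0,
                        round_half_up(zero_case_upper_bound(n_eval)),
                    )
                else:
                    ci = exact_binomial_ci(n_cases, n_eval)
                rate = incidence_rate(n_cases, py)
                cells.append(
                    IncidenceCell(
                        drug=drug,
                        database=database,
                        category=cat,
                        stratum=stratum,
                        n_cases=n_cases,
                        n_evaluated=n_eval,
                        person_years=py,
                        cum_inc_pct=cumulative_incidence(n_cases, n_eval),
                        cum_inc_ci=ci,
                        rate_per_100py=rate if isinstance(rate, str) else rate[0],
                        rate_ci=rate if isinstance(rate, str) else rate[1],
                        one_sided_zero_bound=zero,
                    )
                )
    return cells
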