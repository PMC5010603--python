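"""Liver-chemistry elevation classification, Hy's-law and DILI screening.

Lab values are analyzed as multiples of each row's upper limit of normal
(xULN).  The threshold catalog enumerates the surveillance categories:
transaminase (ALT or AST) bands and open thresholds, alkaline phosphatase
(ALP) and total bilirubin thresholds.  A patient whose baseline multiple
already meets a category's lower threshold is ineligible for that
category's analysis.  First elevations are detected among follow-up labs
dated inside exposure episodes of the index drug; the DILI screen uses
the wider any-anti-VEGF exposure span plus a 90-day extension.

The laboratory signal for possible Hy's law is ALT or AST >= 3x ULN with
total bilirubin >= 2x ULN and ALP < 2x ULN, evaluated on the same
calendar day.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .cohort_exposure import Episode
from .emr_model import StudyConfig, icd9_matches

__all__ = [
    "ThresholdCategory",
    "ElevationEvent",
    "HysLawEvent",
    "DILIScreenFlag",
    "default_catalog",
    "uln_multiple",
    "baseline_multiple",
    "category_eligibility",
    "detect_first_elevation",
    "detect_hys_law",
    "screen_dili",
]

ONE_DAY = datetime.timedelta(days=1)


@dataclass(frozen=True)
class ThresholdCategory:
    """One analyte plus a ULN-multiple range with inclusivity flags.

    ``analyte`` is one of ALT, AST, ALT_or_AST, ALP, BILI.  A banded
    category (``upper`` present) matches only values inside the band: a
    6.0x ALT is an event for the >=5x-9.99x band but not for >=3x-4.99x.
    """

    analyte: str
    lower: float
    lower_inclusive: bool
    upper: float | None
    upper_inclusive: bool
    label: str

    def __post_init__(self) -> None:
        if self.lower <= 0:
            raise ValueError("lower threshold must be positive")
        if self.upper is not None and self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")

    def contains(self, multiple: float) -> bool:
        if self.lower_inclusive:
            if multiple < self.lower:
                return False
        elif multiple <= self.lower:
            return False
        if self.upper is not None:
            if self.upper_inclusive:
                if multiple > self.upper:
                    return False
            elif multiple >= self.upper:
                return False
        return True

    def meets_lower(self, multiple: float) -> bool:
        """Whether ``multiple`` is at or above the category's lower threshold."""
        return multiple >= self.lower if self.lower_inclusive else multiple > self.lower


def _band(analyte: str, lo: float, hi: float, label: str) -> ThresholdCategory:
    # Printed bands like ">=3x-4.99x" are half-open [lo, next threshold)
    return ThresholdCategory(analyte, lo, True, hi, False, label)


def _ge(analyte: str, lo: float, label: str) -> ThresholdCategory:
    return ThresholdCategory(analyte, lo, True, None, False, label)


def _gt(analyte: str, lo: float, label: str) -> ThresholdCategory:
    return ThresholdCategory(analyte, lo, False, None, False, label)


def default_catalog() -> list[ThresholdCategory]:
    """The fixed surveillance catalog of liver-chemistry categories."""
    return [
        _band("ALT_or_AST", 3.0, 5.0, "ALT/AST >=3x-4.99x"),
        _band("ALT_or_AST", 5.0, 10.0, "ALT/AST >=5x-9.99x"),
        _ge("ALT_or_AST", 2.0, "ALT/AST >=2x"),
        _ge("ALT_or_AST", 3.0, "ALT/AST >=3x"),
        _ge("ALT_or_AST", 5.0, "ALT/AST >=5x"),
        _ge("ALT_or_AST", 8.0, "ALT/AST >=8x"),
        _ge("ALT_or_AST", 10.0, "ALT/AST >=10x"),
        _gt("ALP", 1.0, "ALP >1x"),
        _gt("ALP", 2.0, "ALP >2x"),
        _gt("ALP", 3.0, "ALP >3x"),
        _band("ALP", 2.0, 3.0, "ALP >=2x-2.99x"),
        _band("ALP", 3.0, 5.0, "ALP >=3x-4.99x"),
        _ge("ALP", 5.0, "ALP >=5x"),
        _gt("BILI", 1.0, "BILI >1x"),
        _band("BILI", 1.5, 2.0, "BILI >=1.5x-1.99x"),
        _band("BILI", 2.0, 5.0, "BILI >=2x-4.99x"),
        _ge("BILI", 2.0, "BILI >=2x"),
        _ge("BILI", 5.0, "BILI >=5x"),
    ]


@dataclass(frozen=True)
class ElevationEvent:
    patient_id: str
    drug: str
    category: str
    event_date: datetime.date
    days_to_event: int
    multiple: float


@dataclass(frozen=True)
class HysLawEvent:
    patient_id: str
    drug: str
    event_date: datetime.date
    alt_or_ast_multiple: float
    bili_multiple: float
    alp_multiple: float | None


@dataclass(frozen=True)
class DILIScreenFlag:
    patient_id: str
    date: datetime.date
    trigger: str  # "lab_combination" | "icd9_code"
    detail: str


def uln_multiple(value: float, uln: float) -> float:
    """Lab value expressed as a multiple of its upper limit of normal."""
    if not uln > 0:
        raise ValueError(f"ULN must be positive, got {uln!r}")
    return value / uln


def _daily_multiples(labs: pd.DataFrame, analyte: str) -> dict[datetime.date, float]:
    """Max xULN multiple per calendar day for one analyte (or ALT/AST max)."""
    if analyte == "ALT_or_AST":
        rows = labs[labs["analyte"].isin(("ALT", "AST"))]
    else:
        rows = labs[labs["analyte"] == analyte]
    daily: dict[datetime.date, float] = {}
    for r in rows.itertuples(index=False):
        m = uln_multiple(r.value, r.uln)
        if r.date not in daily or m > daily[r.date]:
            daily[r.date] = m
    return daily


def baseline_multiple(
    labs: pd.DataFrame,
    analyte: str,
    start: datetime.date,
    window_days: int = 30,
) -> float | None:
    """Maximum xULN multiple in [start - window, start]; None if unmeasured.

    The maximum is the conservative eligibility summary: any baseline
    result at or above a category's lower threshold removes the patient
    from that category's denominator.
    """
    lo = start - datetime.timedelta(days=window_days)
    daily = _daily_multiples(labs, analyte)
    vals = [m for d, m in daily.items() if lo <= d <= start]
    return max(vals) if vals else None


def category_eligibility(
    baseline: float | None, category: ThresholdCategory
) -> bool:
    """Eligible unless the baseline multiple already meets the lower threshold."""
    if baseline is None:
        return True
    return not category.meets_lower(baseline)


def _in_episodes(
    date: datetime.date, episodes: Sequence[Episode], first_episode_only: bool
) -> bool:
    eps = episodes[:1] if first_episode_only else episodes
    return any(ep.covers(date) for ep in eps)


def detect_first_elevation(
    labs: pd.DataFrame,
    category: ThresholdCategory,
    episodes: Sequence[Episode],
    start: datetime.date,
    drug: str = "",
    patient_id: str = "",
    first_episode_only: bool = False,
) -> ElevationEvent | None:
    """First follow-up lab inside an exposure episode matching the category.

    Follow-up begins the day after start (labs on the start date are
    baseline); labs falling in treatment gaps between episodes do not
    qualify.
    """
    daily = _daily_multiples(labs, category.analyte)
    for d in sorted(daily):
        if d <= start or not _in_episodes(d, episodes, first_episode_only):
            continue
        if category.contains(daily[d]):
            return ElevationEvent(
                patient_id=patient_id,
                drug=drug,
                category=category.label,
                event_date=d,
                days_to_event=(d - start).days,
                multiple=daily[d],
            )
    return None


def hys_law_combination(
    alt_or_ast: float | None, bili: float | None, alp: float | None, alp_required: bool = True
) -> bool:
    """The laboratory triple: ALT/AST >=3x, bilirubin >=2x, ALP <2x."""
    if alt_or_ast is None or bili is None:
        return False
    if alt_or_ast < 3.0 or bili < 2.0:
        return False
    if alp is None:
        return not alp_required
    return alp < 2.0


def detect_hys_law(
    labs: pd.DataFrame,
    episodes: Sequence[Episode],
    start: datetime.date,
    drug: str = "",
    patient_id: str = "",
    window_days: int = 0,
    alp_required: bool = True,
    first_episode_only: bool = False,
) -> HysLawEvent | None:
    """Earliest follow-up day satisfying the Hy's-law laboratory triple.

    With ``window_days`` = 0 all three analytes must be evaluated on the
    same calendar day; a positive window lets the bilirubin and ALP
    qualifiers come from nearby days.  When ALP is unmeasured the
    combination is unverifiable and (by default) not satisfied.
    """
    aa = _daily_multiples(labs, "ALT_or_AST")
    bili = _daily_multiples(labs, "BILI")
    alp = _daily_multiples(labs, "ALP")
    w = datetime.timedelta(days=window_days)

    def near(daily: dict[datetime.date, float], d: datetime.date) -> float | None:
        if window_days == 0:
            return daily.get(d)
        cand = [m for dd, m in daily.items() if abs((dd - d).days) <= window_days]
        return max(cand) if cand else None

    for d in sorted(aa):
        if d <= start or not _in_episodes(d, episodes, first_episode_only):
            continue
        b, p = near(bili, d), near(alp, d)
        if hys_law_combination(aa[d], b, p, alp_required):
            return HysLawEvent(
                patient_id=patient_id,
                drug=drug,
                event_date=d,
                alt_or_ast_multiple=aa[d],
                bili_multiple=b,  # type: ignore[arg-type]
                alp_multiple=p,
            )
    return None


def baseline_hys_law(
    labs: pd.DataFrame,
    start: datetime.date,
    window_days: int = 30,
    alp_required: bool = True,
) -> bool:
    """Whether the Hy's-law triple already occurs in the baseline window."""
    lo = start - datetime.timedelta(days=window_days)
    aa = _daily_multiples(labs, "ALT_or_AST")
    bili = _daily_multiples(labs, "BILI")
    alp = _daily_multiples(labs, "ALP")
    for d, m in aa.items():
        if lo <= d <= start and hys_law_combination(m, bili.get(d), alp.get(d), alp_required):
            return True
    return False


def screen_dili(
    diagnoses: pd.DataFrame,
    labs: pd.DataFrame,
    span_start: datetime.date,
    span_end: datetime.date,
    dili_codes: Sequence[str],
    extension_days: int = 90,
    patient_id: str = "",
) -> list[DILIScreenFlag]:
    """DILI screening flags over the any-anti-VEGF exposure span + 90 days.

    Flags arise from (a) same-day ALT >3x ULN with bilirubin >2x ULN, or
    (b) any configured ICD-9 code (prefix match, e.g. 570.x), dated in
    [span start, span end + extension].
    """
    hi = span_end + datetime.timedelta(days=extension_days)
    flags: list[DILIScreenFlag] = []

    alt = _daily_multiples(labs, "ALT")
    bili = _daily_multiples(labs, "BILI")
    for d in sorted(set(alt) & set(bili)):
        if span_start <= d <= hi and alt[d] > 3.0 and bili[d] > 2.0:
            flags.append(
                DILIScreenFlag(
                    patient_id,
                    d,
                    "lab_combination",
                    f"ALT {alt[d]:.2f}x / BILI {bili[d]:.2f}x",
                )
            )

    for r in diagnoses.sort_values("date", kind="stable").itertuples(index=False):
        if span_start <= r.date <= hi and any(
            icd9_matches(r.icd9, c) for c in dili_codes
        ):
            flags.append(DILIScreenFlag(patient_id, r.date, "icd9_code", r.icd9))
    flags.sort(key=lambda f: (f.date, f.trigger))
    return flags
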