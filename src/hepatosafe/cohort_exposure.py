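"""New-user cohort selection, treatment-episode construction, baseline variables.

A treatment episode ("drug era") is a continuous course of one anti-VEGF
drug: dated exposure intervals from successive prescriptions or
administrations are merged whenever the uncovered gap between them is at
most 30 days; a longer gap ends one episode and starts the next.
Initiation of an alternate RCC treatment, with no further index-drug
record on or after that date, truncates the current episode to the day
before the alternate start and ends episode building.

Cohort entry ("new user") is the first observed record of each anti-VEGF
drug, subject to: start inside the accrual window, an RCC diagnosis on or
before start, age >= 18, at least one ALT and one bilirubin result in the
30 days up to and including start, and no concurrent other anti-VEGF
exposure covering the start date.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .emr_model import EMRDataset, StudyConfig, icd9_matches

__all__ = [
    "Episode",
    "CohortEntry",
    "Exclusion",
    "assign_exposure_interval",
    "build_treatment_episodes",
    "select_new_users",
    "derive_line_of_therapy",
    "derive_metastases",
    "derive_concomitant_meds",
]

ONE_DAY = datetime.timedelta(days=1)


@dataclass(frozen=True)
class Episode:
    """A continuous course of one drug for one patient; endpoints inclusive."""

    patient_id: str
    drug: str
    start: datetime.date
    end: datetime.date
    truncated_by: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"episode start {self.start} after end {self.end}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def covers(self, date: datetime.date) -> bool:
        return self.start <= date <= self.end


@dataclass
class CohortEntry:
    """One (patient, anti-VEGF drug) new-user cohort row; start = baseline."""

    patient_id: str
    drug: str
    start_date: datetime.date
    age_at_start: int
    sex: str
    line_of_therapy: int
    metastasis_sites: frozenset[str]
    concomitant_meds: frozenset[str]


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    drug: str
    reason: str


def assign_exposure_interval(
    drug: str,
    date: datetime.date,
    days_supply: int | None,
    config: StudyConfig,
) -> tuple[datetime.date, datetime.date]:
    """Dated coverage interval for one drug record, endpoints inclusive.

    The recorded days-supply is honored when present; otherwise the
    drug's imputed duration applies (e.g. 28 days per sunitinib
    prescription, 14 days per bevacizumab administration).
    """
    spec = config.drug_spec(drug)  # KeyError for unknown drug
    if days_supply is None or (isinstance(days_supply, float) and pd.isna(days_supply)):
        d = spec.imputed_duration_days
    else:
        d = int(days_supply)
    if d < 1:
        raise ValueError(f"non-positive duration {d} for {drug}")
    return date, date + datetime.timedelta(days=d - 1)


def build_treatment_episodes(
    intervals: Sequence[tuple[datetime.date, datetime.date]],
    alternate_starts: Sequence[tuple[str, datetime.date]] = (),
    gap_days: int = 30,
    patient_id: str = "",
    drug: str = "",
) -> list[Episode]:
    """Merge exposure intervals into episodes; apply alternate-drug truncation.

    ``intervals`` must be sorted by start.  The gap between an interval
    ending on day e and the next starting on day s is ``s - e - 1`` days
    (exclusive of both endpoints); the episode continues iff the gap is at
    most ``gap_days``.  An alternate RCC treatment starting at date t with
    no index-drug interval starting on or after t cuts all coverage at
    t - 1 and marks the episode it cut as truncated.
    """
    if not intervals:
        return []
    for (a, _), (b, _) in zip(intervals, intervals[1:]):
        if b < a:
            raise ValueError("intervals must be sorted by start date")

    # Effective truncation point: earliest alternate start not followed
    # (on or after it) by any index-drug record.
    cutoff: datetime.date | None = None
    truncator: str | None = None
    starts = [s for s, _ in intervals]
    for alt_drug, t in sorted(alternate_starts, key=lambda x: x[1]):
        if not any(s >= t for s in starts):
            cutoff, truncator = t, alt_drug
            break

    clipped: list[tuple[datetime.date, datetime.date]] = []
    for s, e in intervals:
        if cutoff is not None:
            if s >= cutoff:
                continue
            e = min(e, cutoff - ONE_DAY)
        if s <= e:
            clipped.append((s, e))
    if not clipped:
        return []

    gap = datetime.timedelta(days=gap_days)
    episodes: list[Episode] = []
    cur_s, cur_e = clipped[0]
    for s, e in clipped[1:]:
        if s <= cur_e + gap + ONE_DAY:  # gap (s - cur_e - 1) <= gap_days
            cur_e = max(cur_e, e)
        else:
            episodes.append(Episode(patient_id, drug, cur_s, cur_e))
            cur_s, cur_e = s, e
    episodes.append(Episode(patient_id, drug, cur_s, cur_e))

    if cutoff is not None and episodes and episodes[-1].end == cutoff - ONE_DAY:
        last = episodes[-1]
        episodes[-1] = Episode(patient_id, drug, last.start, last.end, truncated_by=truncator)
    return episodes


def _drug_intervals(
    records: pd.DataFrame, drug: str, config: StudyConfig
) -> list[tuple[datetime.date, datetime.date]]:
    rows = records[records["drug"] == drug].sort_values("date", kind="stable")
    return [
        assign_exposure_interval(drug, r.date, r.days_supply, config)
        for r in rows.itertuples(index=False)
    ]


def episodes_for_patient_drug(
    records: pd.DataFrame,
    patient_id: str,
    drug: str,
    config: StudyConfig,
) -> list[Episode]:
    """Episodes for one (patient, index drug), truncated by other anti-VEGF starts."""
    mine = records[records["patient_id"] == patient_id]
    intervals = _drug_intervals(mine, drug, config)
    alternates = [
        (r.drug, r.date)
        for r in mine.itertuples(index=False)
        if r.drug != drug and r.drug in config.anti_vegf_drugs
    ]
    return build_treatment_episodes(
        intervals, alternates, config.gap_days, patient_id, drug
    )


def derive_line_of_therapy(
    prior_treatments: Iterable[tuple[str, datetime.date]],
    start: datetime.date,
    regimen_window_days: int = 30,
) -> int:
    """Ordinal line of the index regimen: 1 + number of distinct prior regimens.

    Antineoplastic drugs whose first starts fall within
    ``regimen_window_days`` of one another are grouped as one regimen
    (combination therapy); each further group counts as an additional
    prior line.
    """
    first_start: dict[str, datetime.date] = {}
    for drug, date in prior_treatments:
        if date >= start:
            raise ValueError("prior treatment dates must precede the index start")
        if drug not in first_start or date < first_start[drug]:
            first_start[drug] = date
    dates = sorted(first_start.values())
    n_regimens = 0
    anchor: datetime.date | None = None
    window = datetime.timedelta(days=regimen_window_days)
    for d in dates:
        if anchor is None or d - anchor > window:
            n_regimens += 1
            anchor = d
    return 1 + n_regimens


def derive_metastases(
    diagnoses: pd.DataFrame,
    start: datetime.date,
    config: StudyConfig,
) -> frozenset[str]:
    """Metastasis site flags from secondary-malignancy codes on or before start."""
    sites: set[str] = set()
    for r in diagnoses.itertuples(index=False):
        if r.date > start:
            continue
        code = r.icd9
        mapped = None
        for entry, site in config.metastasis_code_map.items():
            if icd9_matches(code, entry):
                mapped = site
                break
        if mapped is not None:
            sites.add(mapped)
        elif any(icd9_matches(code, p) for p in config.metastasis_prefixes):
            sites.add("other")
    return frozenset(sites) if sites else frozenset({"none"})


def derive_concomitant_meds(
    drug_records: pd.DataFrame,
    episodes: Sequence[Episode],
    start: datetime.date,
    index_drug: str,
    baseline_window_days: int = 30,
) -> frozenset[str]:
    """Non-index drugs recorded in the 30 days up to start or during exposure."""
    window_lo = start - datetime.timedelta(days=baseline_window_days)
    meds: set[str] = set()
    for r in drug_records.itertuples(index=False):
        if r.drug == index_drug:
            continue
        if window_lo <= r.date <= start or any(ep.covers(r.date) for ep in episodes):
            meds.add(r.drug)
    return frozenset(meds)


def select_new_users(
    dataset: EMRDataset,
    config: StudyConfig,
) -> tuple[list[CohortEntry], list[Exclusion]]:
    """Select the new-user cohort for each anti-VEGF drug.

    One candidate per (patient, drug) at the first observed record of
    that drug; a patient may enter under several drugs at different
    times.  Failed candidates are returned with a reason code
    (``accrual_window`` / ``no_rcc_diagnosis`` / ``age`` /
    ``missing_baseline_lab`` / ``concurrent_anti_vegf``), checked in that
    order.
    """
    entries: list[CohortEntry] = []
    exclusions: list[Exclusion] = []
    birth = dict(zip(dataset.patients["patient_id"], dataset.patients["birth_date"]))
    sex = dict(zip(dataset.patients["patient_id"], dataset.patients["sex"]))
    window = datetime.timedelta(days=config.baseline_window_days)

    empty_dx = dataset.diagnoses.iloc[0:0]
    empty_labs = dataset.lab_results.iloc[0:0]
    dx_by = {pid: df for pid, df in dataset.diagnoses.groupby("patient_id", sort=False)}
    labs_by = {pid: df for pid, df in dataset.lab_results.groupby("patient_id", sort=False)}

    records = dataset.drug_records
    for pid, pat_records in records.groupby("patient_id", sort=True):
        pat_dx = dx_by.get(pid, empty_dx)
        pat_labs = labs_by.get(pid, empty_labs)
        for drug in config.anti_vegf_drugs:
            mine = pat_records[pat_records["drug"] == drug]
            if mine.empty:
                continue
            start = min(mine["date"])

            if not (config.accrual_start <= start <= config.accrual_end):
                exclusions.append(Exclusion(pid, drug, "accrual_window"))
                continue
            has_rcc = any(
                r.date <= start and any(icd9_matches(r.icd9, c) for c in config.rcc_codes)
                for r in pat_dx.itertuples(index=False)
            )
            if not has_rcc:
                exclusions.append(Exclusion(pid, drug, "no_rcc_diagnosis"))
                continue
            age = _age_on(birth[pid], start)
            if age < 18:
                exclusions.append(Exclusion(pid, drug, "age"))
                continue
            base = pat_labs[
                (pat_labs["date"] >= start - window) & (pat_labs["date"] <= start)
            ]
            analytes = set(base["analyte"])
            if "ALT" not in analytes or "BILI" not in analytes:
                exclusions.append(Exclusion(pid, drug, "missing_baseline_lab"))
                continue
            concurrent = False
            for other in config.anti_vegf_drugs:
                if other == drug:
                    continue
                other_eps = build_treatment_episodes(
                    _drug_intervals(pat_records, other, config),
                    gap_days=config.gap_days,
                    patient_id=pid,
                    drug=other,
                )
                if any(ep.covers(start) for ep in other_eps):
                    concurrent = True
                    break
            if concurrent:
                exclusions.append(Exclusion(pid, drug, "concurrent_anti_vegf"))
                continue

            alternates = [
                (r.drug, r.date)
                for r in pat_records.itertuples(index=False)
                if r.drug != drug and r.drug in config.anti_vegf_drugs
            ]
            episodes = build_treatment_episodes(
                _drug_intervals(pat_records, drug, config),
                alternates,
                config.gap_days,
                pid,
                drug,
            )
            prior = [
                (r.drug, r.date)
                for r in pat_records.itertuples(index=False)
                if r.date < start and r.drug in config.antineoplastic_drugs and r.drug != drug
            ]
            entries.append(
                CohortEntry(
                    patient_id=pid,
                    drug=drug,
                    start_date=start,
                    age_at_start=age,
                    sex=sex[pid],
                    line_of_therapy=derive_line_of_therapy(
                        prior, start, config.regimen_window_days
                    ),
                    metastasis_sites=derive_metastases(pat_dx, start, config),
                    concomitant_meds=derive_concomitant_meds(
                        pat_records, episodes, start, drug, config.baseline_window_days
                    ),
                )
            )
    return entries, exclusions


def _age_on(birth: datetime.date, date: datetime.date) -> int:
    age = date.year - birth.year
    if (date.month, date.day) < (birth.month, birth.day):
        age -= 1
    return age
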