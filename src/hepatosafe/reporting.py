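"""End-to-end study orchestration: raw tables to report tables.

``run_study`` chains cohort selection, episode construction, outcome
classification, and incidence estimation into a single deterministic
report; ``render_tables`` writes the report as CSV and/or markdown.
All randomness lives in the synthetic generator — identical inputs and
configuration yield identical report tables.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cohort_exposure import (
    CohortEntry,
    Episode,
    Exclusion,
    assign_exposure_interval,
    build_treatment_episodes,
    select_new_users,
)
from .emr_model import EMRDataset, StudyConfig
from .incidence_stats import (
    UNDEFINED,
    IncidenceCell,
    PatientCategoryRecord,
    TimeToEventSummary,
    build_incidence_table,
    person_time,
    time_to_event_summary,
)
from .lc_outcomes import (
    DILIScreenFlag,
    ElevationEvent,
    HysLawEvent,
    ThresholdCategory,
    baseline_hys_law,
    baseline_multiple,
    category_eligibility,
    default_catalog,
    detect_first_elevation,
    detect_hys_law,
    screen_dili,
)

__all__ = ["StudyReport", "run_study", "render_tables", "HYS_LABEL", "TTE_CATEGORIES"]

HYS_LABEL = "Possible Hy's law"

#: Categories summarized as time-to-event (plus the Hy's-law combination).
TTE_CATEGORIES = ("ALT/AST >=3x", "BILI >=2x")


@dataclass
class StudyReport:
    """Everything the surveillance run produces, plus reproducibility metadata."""

    database: str
    cohort: list[CohortEntry]
    exclusions: list[Exclusion]
    episodes: dict[tuple[str, str], list[Episode]]
    patient_records: list[PatientCategoryRecord]
    incidence_cells: list[IncidenceCell]
    time_to_event: list[TimeToEventSummary]
    elevation_events: list[ElevationEvent]
    hys_events: list[HysLawEvent]
    dili_flags: list[DILIScreenFlag]
    baseline_table: pd.DataFrame
    stage_log: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def _config_hash(config: StudyConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def _baseline_table(cohort: Sequence[CohortEntry]) -> pd.DataFrame:
    """Per-drug demographic and clinical baseline summary (Table-1 style)."""
    rows = []
    drugs = sorted({e.drug for e in cohort})
    sites = ("lung", "liver", "bone_or_marrow", "brain_or_spinal_cord", "adrenal", "none")
    for drug in drugs:
        grp = [e for e in cohort if e.drug == drug]
        n = len(grp)
        ages = [e.age_at_start for e in grp]
        mean = sum(ages) / n
        sd = (sum((a - mean) ** 2 for a in ages) / (n - 1)) ** 0.5 if n > 1 else 0.0
        row = {
            "drug": drug,
            "n": n,
            "age_mean": round(mean, 1),
            "age_sd": round(sd, 1),
            "male_n": sum(1 for e in grp if e.sex == "male"),
            "male_pct": round(100.0 * sum(1 for e in grp if e.sex == "male") / n, 1),
        }
        for site in sites:
            row[f"met_{site}"] = sum(1 for e in grp if site in e.metastasis_sites)
        row["first_line"] = sum(1 for e in grp if e.line_of_therapy == 1)
        row["second_line"] = sum(1 for e in grp if e.line_of_therapy == 2)
        row["third_line_plus"] = sum(1 for e in grp if e.line_of_therapy >= 3)
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    dataset: EMRDataset,
    config: StudyConfig,
    catalog: Sequence[ThresholdCategory] | None = None,
    database: str | None = None,
) -> StudyReport:
    """Run the full common-protocol analysis on one database snapshot."""
    if catalog is None:
        catalog = default_catalog()
    database = database or dataset.provenance
    log: list[dict] = []

    cohort, exclusions = select_new_users(dataset, config)
    log.append(
        {
            "stage": "select_new_users",
            "candidates": len(cohort) + len(exclusions),
            "included": len(cohort),
            "excluded": len(exclusions),
        }
    )

    empty_dx = dataset.diagnoses.iloc[0:0]
    empty_labs = dataset.lab_results.iloc[0:0]
    dx_by = {pid: df for pid, df in dataset.diagnoses.groupby("patient_id", sort=False)}
    labs_by = {pid: df for pid, df in dataset.lab_results.groupby("patient_id", sort=False)}
    rx_by = {pid: df for pid, df in dataset.drug_records.groupby("patient_id", sort=False)}

    episodes: dict[tuple[str, str], list[Episode]] = {}
    records: list[PatientCategoryRecord] = []
    elevation_events: list[ElevationEvent] = []
    hys_events: list[HysLawEvent] = []

    for entry in cohort:
        pid, drug, start = entry.patient_id, entry.drug, entry.start_date
        pat_rx = rx_by[pid]
        intervals = [
            assign_exposure_interval(r.drug, r.date, r.days_supply, config)
            for r in pat_rx[pat_rx["drug"] == drug]
            .sort_values("date", kind="stable")
            .itertuples(index=False)
        ]
        alternates = [
            (r.drug, r.date)
            for r in pat_rx.itertuples(index=False)
            if r.drug != drug and r.drug in config.anti_vegf_drugs
        ]
        eps = build_treatment_episodes(intervals, alternates, config.gap_days, pid, drug)
        episodes[(pid, drug)] = eps
        labs = labs_by.get(pid, empty_labs)

        for cat in catalog:
            base = baseline_multiple(labs, cat.analyte, start, config.baseline_window_days)
            eligible = category_eligibility(base, cat)
            event = None
            if eligible:
                event = detect_first_elevation(
                    labs,
                    cat,
                    eps,
                    start,
                    drug=drug,
                    patient_id=pid,
                    first_episode_only=config.first_episode_only,
                )
            py = person_time(
                eps,
                event.event_date if event else None,
                config.year_length_days,
            )
            if event is not None:
                elevation_events.append(event)
            records.append(
                PatientCategoryRecord(
                    patient_id=pid,
                    drug=drug,
                    category=cat.label,
                    line_of_therapy=entry.line_of_therapy,
                    eligible=eligible,
                    event_days=event.days_to_event if event else None,
                    person_years=py,
                )
            )

        hys_eligible = not baseline_hys_law(
            labs, start, config.baseline_window_days, config.alp_required
        )
        hys = None
        if hys_eligible:
            hys = detect_hys_law(
                labs,
                eps,
                start,
                drug=drug,
                patient_id=pid,
                window_days=config.hys_law_window_days,
                alp_required=config.alp_required,
                first_episode_only=config.first_episode_only,
            )
        if hys is not None:
            hys_events.append(hys)
        records.append(
            PatientCategoryRecord(
                patient_id=pid,
                drug=drug,
                category=HYS_LABEL,
                line_of_therapy=entry.line_of_therapy,
                eligible=hys_eligible,
                event_days=(hys.event_date - start).days if hys else None,
                person_years=person_time(
                    eps, hys.event_date if hys else None, config.year_length_days
                ),
            )
        )
    log.append(
        {
            "stage": "outcomes",
            "patient_category_records": len(records),
            "elevation_events": len(elevation_events),
            "hys_events": len(hys_events),
        }
    )

    order = [c.label for c in catalog] + [HYS_LABEL]
    cells = build_incidence_table(records, database, category_order=order)

    tte: list[TimeToEventSummary] = []
    drugs = sorted({e.drug for e in cohort})
    for drug in drugs:
        for cat in (*TTE_CATEGORIES, HYS_LABEL):
            days = [
                r.event_days
                for r in records
                if r.drug == drug and r.category == cat and r.event_days is not None
            ]
            summary = time_to_event_summary(days, drug=drug, category=cat)
            if summary is None:
                summary = TimeToEventSummary(drug, cat, 0, float("nan"), float("nan"))
            tte.append(summary)

    dili_flags: list[DILIScreenFlag] = []
    for pid in sorted({e.patient_id for e in cohort}):
        pat_rx = rx_by[pid]
        spans = [
            assign_exposure_interval(r.drug, r.date, r.days_supply, config)
            for r in pat_rx.itertuples(index=False)
            if r.drug in config.anti_vegf_drugs
        ]
        span_start = min(s for s, _ in spans)
        span_end = max(e for _, e in spans)
        dili_flags.extend(
            screen_dili(
                dx_by.get(pid, empty_dx),
                labs_by.get(pid, empty_labs),
                span_start,
                span_end,
                config.dili_codes,
                config.dili_extension_days,
                patient_id=pid,
            )
        )
    log.append({"stage": "dili_screen", "patients": len({e.patient_id for e in cohort}),
                "flags": len(dili_flags)})

    return StudyReport(
        database=database,
        cohort=list(cohort),
        exclusions=list(exclusions),
        episodes=episodes,
        patient_records=records,
        incidence_cells=cells,
        time_to_event=tte,
        elevation_events=elevation_events,
        hys_events=hys_events,
        dili_flags=dili_flags,
        baseline_table=_baseline_table(cohort),
        stage_log=log,
        metadata={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
            "generated_at": datetime.datetime.now().isoformat(timespec="seconds"),
        },
    )


def _fmt_ci(ci: tuple[float, float] | str) -> str:
    if isinstance(ci, str):
        return "NA"
    return f"({ci[0]}, {ci[1]})"


def _cells_frame(cells: Sequence[IncidenceCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append(
            {
                "database": c.database,
                "drug": c.drug,
                "category": c.category,
                "stratum": c.stratum,
                "n_cases": c.n_cases,
                "n_evaluated": c.n_evaluated,
                "person_years": round(c.person_years, 3),
                "cum_inc_pct": c.cum_inc_pct,
                "cum_inc_ci_lo": "NA" if isinstance(c.cum_inc_ci, str) else c.cum_inc_ci[0],
                "cum_inc_ci_hi": "NA" if isinstance(c.cum_inc_ci, str) else c.cum_inc_ci[1],
                "rate_per_100py": c.rate_per_100py,
                "rate_ci_lo": "NA" if isinstance(c.rate_ci, str) else c.rate_ci[0],
                "rate_ci_hi": "NA" if isinstance(c.rate_ci, str) else c.rate_ci[1],
                "zero_case_one_sided": c.one_sided_zero_bound,
            }
        )
    return pd.DataFrame(rows)


def _md_table(headers: Sequence[str], rows: Sequence[Sequence[object]]) -> str:
    lines = ["| " + " | ".join(headers) + " |", "|" + "|".join("---" for _ in headers) + "|"]
    for row in rows:
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def render_tables(
    report: StudyReport,
    directory: Path | str,
    formats: Sequence[str] = ("csv",),
) -> dict[str, Path]:
    """Write the report tables; returns the mapping of artifact name to path."""
    for fmt in formats:
        if fmt not in ("csv", "markdown"):
            raise ValueError(f"unsupported format: {fmt}")
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    cells = _cells_frame(report.incidence_cells)
    cohort = pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "drug": e.drug,
                "start_date": e.start_date.isoformat(),
                "age_at_start": e.age_at_start,
                "sex": e.sex,
                "line_of_therapy": e.line_of_therapy,
                "metastasis_sites": ";".join(sorted(e.metastasis_sites)),
                "concomitant_meds": ";".join(sorted(e.concomitant_meds)),
            }
            for e in report.cohort
        ],
        columns=[
            "patient_id",
            "drug",
            "start_date",
            "age_at_start",
            "sex",
            "line_of_therapy",
            "metastasis_sites",
            "concomitant_meds",
        ],
    )
    exclusions = pd.DataFrame(
        [
            {"patient_id": x.patient_id, "drug": x.drug, "reason": x.reason}
            for x in report.exclusions
        ],
        columns=["patient_id", "drug", "reason"],
    )
    tte = pd.DataFrame(
        [
            {
                "drug": s.drug,
                "category": s.category,
                "n_events": s.n_events,
                "mean_days": "NA" if s.n_events == 0 else s.mean_days,
                "median_days": "NA" if s.n_events == 0 else s.median_days,
            }
            for s in report.time_to_event
        ],
        columns=["drug", "category", "n_events", "mean_days", "median_days"],
    )
    dili = pd.DataFrame(
        [
            {"patient_id": f.patient_id, "date": f.date.isoformat(), "trigger": f.trigger,
             "detail": f.detail}
            for f in report.dili_flags
        ],
        columns=["patient_id", "date", "trigger", "detail"],
    )
    events = pd.DataFrame(
        [
            {
                "patient_id": ev.patient_id,
                "drug": ev.drug,
                "category": ev.category,
                "event_date": ev.event_date.isoformat(),
                "days_to_event": ev.days_to_event,
                "multiple": round(ev.multiple, 4),
            }
            for ev in report.elevation_events
        ],
        columns=["patient_id", "drug", "category", "event_date", "days_to_event", "multiple"],
    )

    if "csv" in formats:
        for name, df in (
            ("incidence", cells),
            ("baseline", report.baseline_table),
            ("time_to_event", tte),
            ("cohort", cohort),
            ("exclusions", exclusions),
            ("dili_flags", dili),
            ("events", events),
        ):
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            written[name] = path

    if "markdown" in formats:
        md_rows = []
        for c in report.incidence_cells:
            if c.stratum != "overall":
                continue
            if c.n_evaluated == 0:
                summary = "n/a"
                rate = "n/a"
            else:
                summary = f"{c.n_cases}/{c.n_evaluated}: {c.cum_inc_pct} {_fmt_ci(c.cum_inc_ci)}"
                rate = (
                    f"{c.rate_per_100py} {_fmt_ci(c.rate_ci)}"
                    if not isinstance(c.rate_per_100py, str)
                    else "n/a"
                )
            md_rows.append([c.drug, c.category, summary, rate])
        md = "# Incidence of liver-chemistry elevations\n\n"
        md += _md_table(
            ["Drug", "Category", "Cases/evaluated: cum. inc. % (95% CI)", "Rate /100py (95% CI)"],
            md_rows,
        )
        md += "\nZero-case cells report the one-sided 97.5% upper bound.\n"
        path = out / "incidence.md"
        path.write_text(md)
        written["incidence_md"] = path

    meta_path = out / "run_metadata.json"
    meta = dict(report.metadata)
    meta["stage_log"] = report.stage_log
    meta_path.write_text(json.dumps(meta, indent=2))
    written["metadata"] = meta_path
    return written
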