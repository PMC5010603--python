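"""Synthetic EMR generator emulating the surveillance data-generating setting.

Every generated patient is, by construction, cohort-eligible: an RCC
diagnosis precedes the first anti-VEGF record, baseline ALT and
bilirubin fall inside the 30-day baseline window, and age is 40-85 at
start.  Exposure is a refill chain (imputed-duration records separated
by small gaps); follow-up labs arrive on a fixed visit schedule.

Liver-chemistry elevations are realized event-time-first: a latent
crossing time is drawn from the configured constant hazard (exponential,
clock starting at drug initiation) and the qualifying lab value is
placed at the next scheduled visit at or after that time.  Detection is
therefore measurement-limited — a sparse lab schedule delays or misses
events — which is exactly the attenuation mechanism surveillance from
routine-care labs is subject to, and tests can quantify it by varying
the visit interval.  Between-event lab noise is i.i.d. log-normal on the
ULN-multiple scale, capped below 2x ULN so that with all hazards zero no
follow-up result crosses any 2x threshold.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .emr_model import (
    ANALYTES,
    EMRDataset,
    StudyConfig,
    default_study_config,
    empty_dataset,
)

__all__ = ["SimulationConfig", "generate_dataset", "generate_worked_fixture"]

#: Laboratory upper limits of normal used for generated results (lab units).
DEFAULT_ULN = {"ALT": 40.0, "AST": 40.0, "ALP": 120.0, "BILI": 1.2}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic data-generating process.

    ``elevation_hazards`` maps (drug, analyte) to a constant hazard, in
    events per person-year while exposed, of the analyte crossing its
    ``elevation_multiples`` threshold.  ``hys_law_fraction`` is the share
    of ALT/AST elevation events accompanied, on the detection day, by
    bilirubin >= 2x and ALP < 2x (the Hy's-law laboratory triple).
    """

    n_patients_per_drug: int = 50
    study: StudyConfig = field(default_factory=default_study_config)
    treatment_days: int = 240
    refill_gap_mean_days: float = 3.0
    lab_interval_days: int = 30
    panel_analytes: tuple[str, ...] = ("ALT", "AST", "ALP", "BILI")
    baseline_median_multiple: Mapping[str, float] = field(
        default_factory=lambda: {a: 0.6 for a in ANALYTES}
    )
    baseline_sigma: float = 0.25
    noise_cap_multiple: float = 1.95
    elevation_hazards: Mapping[tuple[str, str], float] = field(default_factory=dict)
    elevation_multiples: Mapping[str, float] = field(
        default_factory=lambda: {"ALT": 3.0, "AST": 3.0, "ALP": 2.0, "BILI": 2.0}
    )
    hys_law_fraction: float = 0.0
    switch_probability: float = 0.0
    dili_code_rate: float = 0.0
    male_fraction: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        for key, h in self.elevation_hazards.items():
            if h < 0:
                raise ValueError(f"negative elevation hazard for {key}")
        for name in ("hys_law_fraction", "switch_probability", "male_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dili_code_rate < 0:
            raise ValueError("dili_code_rate must be non-negative")
        if self.n_patients_per_drug < 0:
            raise ValueError("n_patients_per_drug must be non-negative")


def _noise_multiple(rng: np.random.Generator, cfg: SimulationConfig, analyte: str) -> float:
    m = cfg.baseline_median_multiple.get(analyte, 0.6)
    v = float(np.exp(np.log(m) + cfg.baseline_sigma * rng.standard_normal()))
    return min(v, cfg.noise_cap_multiple)


def generate_dataset(sim: SimulationConfig) -> EMRDataset:
    """Draw a full four-table dataset; deterministic for a fixed seed."""
    rng = np.random.default_rng(sim.seed)
    study = sim.study
    accrual_days = (study.accrual_end - study.accrual_start).days
    day = datetime.timedelta(days=1)
    year = study.year_length_days

    patients, diagnoses, drugs_rows, labs = [], [], [], []

    for drug in study.anti_vegf_drugs:
        spec = study.drug_spec(drug)
        for i in range(sim.n_patients_per_drug):
            pid = f"{drug[:3]}-{i:05d}"
            start = study.accrual_start + day * int(rng.integers(0, accrual_days + 1))
            age = int(rng.integers(40, 86))
            birth = datetime.date(start.year - age, 1, 1)
            sex = "male" if rng.random() < sim.male_fraction else "female"
            patients.append((pid, birth, sex))
            diagnoses.append(
                (pid, start - day * int(rng.integers(30, 400)), "189.0")
            )

            # refill chain covering ~treatment_days of therapy
            rx_starts: list[datetime.date] = []
            t = start
            covered = 0
            while covered < sim.treatment_days:
                rx_starts.append(t)
                drugs_rows.append((pid, drug, t, None, spec.record_kind))
                covered += spec.imputed_duration_days
                gap = int(rng.poisson(sim.refill_gap_mean_days)) if sim.refill_gap_mean_days > 0 else 0
                t = t + day * (spec.imputed_duration_days + gap)
            exposure_end = rx_starts[-1] + day * (spec.imputed_duration_days - 1)

            # baseline panel inside [start - window, start]
            base_offset = int(rng.integers(0, study.baseline_window_days + 1))
            base_date = start - day * base_offset
            for analyte in ("ALT", "BILI"):
                uln = DEFAULT_ULN[analyte]
                labs.append(
                    (pid, base_date, analyte, _noise_multiple(rng, sim, analyte) * uln, uln)
                )

            # visit schedule and latent elevation times
            visits: list[datetime.date] = []
            k = 1
            while True:
                v = start + day * (k * sim.lab_interval_days)
                if v > exposure_end:
                    break
                visits.append(v)
                k += 1

            event_visit: dict[str, int] = {}  # analyte -> visit index of detection
            hys_visit: int | None = None
            for analyte in sim.panel_analytes:
                lam = sim.elevation_hazards.get((drug, analyte), 0.0)
                if lam <= 0:
                    continue
                t_years = float(rng.exponential(1.0 / lam))
                event_date = start + day * int(round(t_years * year))
                if event_date > exposure_end:
                    continue
                idx = next((j for j, v in enumerate(visits) if v >= event_date), None)
                if idx is not None:
                    event_visit[analyte] = idx
            if (
                sim.hys_law_fraction > 0
                and any(a in event_visit for a in ("ALT", "AST"))
                and rng.random() < sim.hys_law_fraction
            ):
                hys_visit = min(
                    event_visit[a] for a in ("ALT", "AST") if a in event_visit
                )

            for j, v in enumerate(visits):
                for analyte in sim.panel_analytes:
                    uln = DEFAULT_ULN[analyte]
                    thr = sim.elevation_multiples.get(analyte, 3.0)
                    if event_visit.get(analyte) == j:
                        mult = thr * float(rng.uniform(1.05, 1.6))
                    elif hys_visit == j and analyte == "BILI":
                        mult = 2.0 * float(rng.uniform(1.05, 1.5))
                    elif hys_visit == j and analyte == "ALP":
                        mult = float(rng.uniform(0.5, 1.5))
                    else:
                        mult = _noise_multiple(rng, sim, analyte)
                    labs.append((pid, v, analyte, mult * uln, uln))
                if hys_visit == j:
                    for analyte in ("BILI", "ALP"):
                        if analyte not in sim.panel_analytes:
                            uln = DEFAULT_ULN[analyte]
                            mult = (
                                2.0 * float(rng.uniform(1.05, 1.5))
                                if analyte == "BILI"
                                else float(rng.uniform(0.5, 1.5))
                            )
                            labs.append((pid, v, analyte, mult * uln, uln))

            if sim.switch_probability > 0 and rng.random() < sim.switch_probability:
                others = [d for d in study.anti_vegf_drugs if d != drug]
                alt = others[int(rng.integers(0, len(others)))]
                alt_start = exposure_end + day * int(rng.integers(31, 91))
                alt_spec = study.drug_spec(alt)
                drugs_rows.append((pid, alt, alt_start, None, alt_spec.record_kind))

            if sim.dili_code_rate > 0:
                t_years = float(rng.exponential(1.0 / sim.dili_code_rate))
                code_date = start + day * int(round(t_years * year))
                if code_date <= exposure_end + day * study.dili_extension_days:
                    codes = study.dili_codes
                    diagnoses.append(
                        (pid, code_date, codes[int(rng.integers(0, len(codes)))])
                    )

    if not patients:
        return empty_dataset(provenance=f"synthetic(seed={sim.seed})")
    ds = EMRDataset(
        patients=pd.DataFrame(patients, columns=["patient_id", "birth_date", "sex"]),
        diagnoses=pd.DataFrame(diagnoses, columns=["patient_id", "date", "icd9"]),
        drug_records=pd.DataFrame(
            drugs_rows, columns=["patient_id", "drug", "date", "days_supply", "kind"]
        ),
        lab_results=pd.DataFrame(
            labs, columns=["patient_id", "date", "analyte", "value", "uln"]
        ),
        provenance=f"synthetic(seed={sim.seed})",
    )
    return ds.validate()


def _fixture_rows() -> tuple[list, list, list, list]:
    """Hand-written 20-patient dataset exercising every protocol edge."""
    D = datetime.date
    patients: list[tuple] = []
    dx: list[tuple] = []
    rx: list[tuple] = []
    labs: list[tuple] = []

    def add_patient(pid: str, birth: D, sex: str = "male") -> None:
        patients.append((pid, birth, sex))

    def add_baseline(pid: str, date: D, alt_mult: float = 0.6, bili_mult: float = 0.5):
        labs.append((pid, date, "ALT", alt_mult * 40.0, 40.0))
        labs.append((pid, date, "BILI", bili_mult * 1.2, 1.2))

    # F01: pazopanib, refill gap of exactly 30 days -> one continuous episode
    add_patient("F01", D(1955, 3, 2))
    dx.append(("F01", D(2009, 11, 1), "189.0"))
    rx.append(("F01", "pazopanib", D(2010, 1, 1), None, "prescription"))
    rx.append(("F01", "pazopanib", D(2010, 3, 2), None, "prescription"))  # gap = 30 d
    add_baseline("F01", D(2009, 12, 20))

    # F02: pazopanib, gap of 31 days -> two episodes
    add_patient("F02", D(1950, 6, 10))
    dx.append(("F02", D(2010, 1, 15), "189.1"))
    rx.append(("F02", "pazopanib", D(2010, 2, 1), None, "prescription"))
    rx.append(("F02", "pazopanib", D(2010, 4, 3), None, "prescription"))  # gap = 31 d
    add_baseline("F02", D(2010, 1, 25))

    # F03: pazopanib truncated by a sunitinib start mid-episode
    add_patient("F03", D(1948, 9, 9))
    dx.append(("F03", D(2010, 2, 1), "189.0"))
    rx.append(("F03", "pazopanib", D(2010, 3, 1), None, "prescription"))
    rx.append(("F03", "sunitinib", D(2010, 3, 16), None, "prescription"))
    add_baseline("F03", D(2010, 2, 20))

    # F04: baseline ALT exactly 3.0x ULN (category-eligibility worked example)
    add_patient("F04", D(1960, 1, 1))
    dx.append(("F04", D(2010, 3, 1), "189.0"))
    rx.append(("F04", "pazopanib", D(2010, 5, 1), None, "prescription"))
    labs.append(("F04", D(2010, 4, 20), "ALT", 120.0, 40.0))  # exactly 3.0x
    labs.append(("F04", D(2010, 4, 20), "BILI", 0.6, 1.2))
    labs.append(("F04", D(2010, 5, 20), "ALT", 240.0, 40.0))  # 6.0x on treatment

    # F05: same-day Hy's-law triple during exposure
    add_patient("F05", D(1957, 7, 4), "female")
    dx.append(("F05", D(2010, 4, 1), "189.0"))
    rx.append(("F05", "sorafenib", D(2010, 6, 1), None, "prescription"))
    add_baseline("F05", D(2010, 5, 25))
    labs.append(("F05", D(2010, 6, 20), "ALT", 140.0, 40.0))  # 3.5x
    labs.append(("F05", D(2010, 6, 20), "BILI", 2.64, 1.2))  # 2.2x
    labs.append(("F05", D(2010, 6, 20), "ALP", 180.0, 120.0))  # 1.5x

    # F06: triple with ALP exactly 2.0x -> Hy's law NOT met
    add_patient("F06", D(1952, 2, 2))
    dx.append(("F06", D(2010, 4, 1), "189.0"))
    rx.append(("F06", "sorafenib", D(2010, 7, 1), None, "prescription"))
    add_baseline("F06", D(2010, 6, 25))
    labs.append(("F06", D(2010, 7, 15), "ALT", 140.0, 40.0))
    labs.append(("F06", D(2010, 7, 15), "BILI", 2.64, 1.2))
    labs.append(("F06", D(2010, 7, 15), "ALP", 240.0, 120.0))  # 2.0x exactly

    # F07: DILI ICD-9 code 91 days after last exposure (outside screen window)
    add_patient("F07", D(1949, 12, 25))
    dx.append(("F07", D(2010, 5, 1), "189.0"))
    rx.append(("F07", "sunitinib", D(2010, 6, 1), None, "prescription"))  # ends 6/28
    add_baseline("F07", D(2010, 5, 20))
    dx.append(("F07", D(2010, 9, 27), "573.3"))  # exposure end + 91 d

    # F08: DILI ICD-9 570.1 (prefix match on 570) inside the exposure span
    add_patient("F08", D(1961, 8, 8))
    dx.append(("F08", D(2010, 5, 1), "189.0"))
    rx.append(("F08", "sunitinib", D(2010, 7, 1), None, "prescription"))
    add_baseline("F08", D(2010, 6, 20))
    dx.append(("F08", D(2010, 7, 10), "570.1"))

    # F09: no bilirubin result in the baseline window -> excluded
    add_patient("F09", D(1958, 4, 18))
    dx.append(("F09", D(2010, 2, 1), "189.0"))
    rx.append(("F09", "pazopanib", D(2010, 4, 1), None, "prescription"))
    labs.append(("F09", D(2010, 3, 25), "ALT", 24.0, 40.0))

    # F10: age 17 at start -> excluded
    add_patient("F10", D(1993, 6, 1))
    dx.append(("F10", D(2010, 7, 1), "189.0"))
    rx.append(("F10", "sunitinib", D(2010, 8, 1), None, "prescription"))
    add_baseline("F10", D(2010, 7, 25))

    # F11: plain eligible bevacizumab user (administrations, 14-day coverage)
    add_patient("F11", D(1954, 10, 10), "female")
    dx.append(("F11", D(2010, 8, 1), "189.0"))
    rx.append(("F11", "bevacizumab", D(2010, 9, 1), None, "administration"))
    rx.append(("F11", "bevacizumab", D(2010, 9, 15), None, "administration"))
    add_baseline("F11", D(2010, 8, 25))

    # F12: plain eligible sunitinib user
    add_patient("F12", D(1947, 1, 30))
    dx.append(("F12", D(2010, 9, 1), "189.0"))
    rx.append(("F12", "sunitinib", D(2010, 10, 1), None, "prescription"))
    add_baseline("F12", D(2010, 9, 20))

    # F13: plain eligible sorafenib user with an on-treatment 2.5x ALT
    add_patient("F13", D(1956, 5, 5))
    dx.append(("F13", D(2010, 10, 1), "189.0"))
    rx.append(("F13", "sorafenib", D(2010, 11, 1), None, "prescription"))
    add_baseline("F13", D(2010, 10, 25))
    labs.append(("F13", D(2010, 11, 20), "ALT", 100.0, 40.0))  # 2.5x

    # F14: recorded days_supply of 90 honored over the imputed duration
    add_patient("F14", D(1951, 3, 3))
    dx.append(("F14", D(2010, 11, 1), "189.0"))
    rx.append(("F14", "pazopanib", D(2010, 12, 1), 90, "prescription"))
    add_baseline("F14", D(2010, 11, 25))

    # F15: second line of therapy (prior sunitinib course)
    add_patient("F15", D(1959, 9, 19))
    dx.append(("F15", D(2010, 1, 1), "189.0"))
    rx.append(("F15", "sunitinib", D(2010, 2, 1), None, "prescription"))
    rx.append(("F15", "pazopanib", D(2010, 6, 1), None, "prescription"))
    add_baseline("F15", D(2010, 5, 25))
    labs.append(("F15", D(2010, 1, 25), "ALT", 24.0, 40.0))
    labs.append(("F15", D(2010, 1, 25), "BILI", 0.6, 1.2))

    # F16: third line (interferon course, then sunitinib course, then pazopanib)
    add_patient("F16", D(1946, 11, 11))
    dx.append(("F16", D(2009, 6, 1), "189.0"))
    rx.append(("F16", "interferon", D(2009, 11, 1), None, "prescription"))
    rx.append(("F16", "sunitinib", D(2010, 3, 1), None, "prescription"))
    rx.append(("F16", "pazopanib", D(2010, 8, 1), None, "prescription"))
    labs.append(("F16", D(2009, 10, 20), "ALT", 24.0, 40.0))
    labs.append(("F16", D(2009, 10, 20), "BILI", 0.6, 1.2))
    add_baseline("F16", D(2010, 7, 25))

    # F17: metastasis codes (lung 197.0, bone 198.5) before start
    add_patient("F17", D(1953, 12, 1), "female")
    dx.append(("F17", D(2010, 10, 1), "189.0"))
    dx.append(("F17", D(2010, 10, 5), "197.0"))
    dx.append(("F17", D(2010, 10, 5), "198.5"))
    rx.append(("F17", "pazopanib", D(2010, 12, 1), None, "prescription"))
    add_baseline("F17", D(2010, 11, 25))

    # F18: concomitant meds — statin 10 d before start, antibiotic in episode 2
    add_patient("F18", D(1950, 4, 14))
    dx.append(("F18", D(2011, 1, 1), "189.0"))
    rx.append(("F18", "pazopanib", D(2011, 2, 1), None, "prescription"))
    rx.append(("F18", "pazopanib", D(2011, 4, 15), None, "prescription"))  # gap 42 d
    rx.append(("F18", "simvastatin", D(2011, 1, 22), None, "prescription"))
    rx.append(("F18", "amoxicillin", D(2011, 4, 20), None, "prescription"))
    rx.append(("F18", "warfarin", D(2010, 12, 31), None, "prescription"))  # 32 d before
    add_baseline("F18", D(2011, 1, 28))

    # F19: ALT 3.5x dated in the >30-day treatment gap -> no elevation event
    add_patient("F19", D(1957, 2, 27))
    dx.append(("F19", D(2011, 2, 1), "189.0"))
    rx.append(("F19", "sunitinib", D(2011, 3, 1), None, "prescription"))  # ends 3/28
    rx.append(("F19", "sunitinib", D(2011, 5, 10), None, "prescription"))  # gap 42 d
    add_baseline("F19", D(2011, 2, 20))
    labs.append(("F19", D(2011, 4, 15), "ALT", 140.0, 40.0))  # in the gap

    # F20: eligible bevacizumab user with an on-treatment BILI 2.5x event
    add_patient("F20", D(1944, 8, 21))
    dx.append(("F20", D(2011, 3, 1), "189.0"))
    rx.append(("F20", "bevacizumab", D(2011, 4, 1), None, "administration"))
    add_baseline("F20", D(2011, 3, 25))
    labs.append(("F20", D(2011, 4, 10), "BILI", 3.0, 1.2))  # 2.5x

    return patients, dx, rx, labs


def generate_worked_fixture() -> EMRDataset:
    """Small handcrafted dataset covering every protocol edge case.

    Includes, among others: a refill gap of exactly 30 days (one episode)
    and of 31 days (two episodes), an alternate-drug truncation, a
    baseline ALT of exactly 3.0x ULN, a same-day Hy's-law triple, and a
    DILI code dated 91 days after last exposure (outside the screen).
    """
    patients, dx, rx, labs = _fixture_rows()
    ds = EMRDataset(
        patients=pd.DataFrame(patients, columns=["patient_id", "birth_date", "sex"]),
        diagnoses=pd.DataFrame(dx, columns=["patient_id", "date", "icd9"]),
        drug_records=pd.DataFrame(
            rx, columns=["patient_id", "drug", "date", "days_supply", "kind"]
        ),
        lab_results=pd.DataFrame(
            labs, columns=["patient_id", "date", "analyte", "value", "uln"]
        ),
        provenance="worked-fixture",
    )
    return ds.validate()
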