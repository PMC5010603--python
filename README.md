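# hepatosafe

Laboratory-based hepatotoxicity surveillance for anti-VEGF therapy in
renal cell carcinoma (RCC), packaged as a tested, reusable pipeline.

Oral tyrosine-kinase inhibitors such as pazopanib carry a boxed warning
for severe hepatotoxicity, and post-marketing surveillance has to work
from routine-care electronic medical records (EMR): prescription and
infusion records, ICD-9 diagnoses, and liver-chemistry (LC) panels with
heterogeneous reference ranges. `hepatosafe` implements a common-protocol
analysis for this setting — new-user cohort selection, treatment-episode
("drug era") construction, LC elevation classification against multiples
of the upper limit of normal (xULN), Hy's-law and drug-induced liver
injury (DILI) screening, and censored person-time incidence estimation —
together with a synthetic EMR generator so every stage is testable
without access to protected health data.

It is intended for pharmacoepidemiologists and safety statisticians who
need a transparent, auditable implementation of these conventions.

## The model

**Cohort.** A new user of drug *d* enters at the first observed record of
*d* (the start date), provided the start falls in the accrual window, an
RCC diagnosis (ICD-9 189.0/189.1) is recorded on or before start, age is
≥ 18, at least one ALT and one total-bilirubin result exist in
[start − 30 d, start], and no other anti-VEGF drug's episode covers the
start date. A patient may enter under several drugs at different times.

**Exposure.** Each record covers `[date, date + duration − 1]`, the
duration being the recorded days-supply or an imputed default (30 d for
pazopanib/sorafenib, 28 d for sunitinib, 14 d per bevacizumab infusion).
Intervals whose uncovered gap is ≤ 30 days merge into one treatment
episode; a longer gap starts a new episode; an alternate RCC treatment
with no later index-drug record truncates the episode at the day before.

**Outcomes.** Lab values are analysed as x = value/ULN per row. The
category catalog spans ALT-or-AST (bands ≥3x–4.99x, ≥5x–9.99x and open
thresholds ≥2x…≥10x), ALP (>1x…≥5x) and bilirubin (>1x…≥5x). A patient
whose maximum baseline multiple already meets a category's lower
threshold is ineligible for that category. The Hy's-law laboratory
signal is ALT or AST ≥3x with bilirubin ≥2x and ALP <2x on the same day;
the DILI screen flags same-day ALT >3x with bilirubin >2x, or ICD-9
codes 277.4, 570.x, 572.8, 573.3, 573.8, 576.8, 782.4, over the
any-anti-VEGF exposure span plus 90 days.

**Statistics.** Cumulative incidence is n/N with exact (Clopper–Pearson)
95% limits, `100·(1 − 0.025^(1/N))` as the one-sided 97.5% bound for
zero-case cells; incidence rates are cases per 100 person-years with
exposure summed over episodes and censored at the first qualifying
elevation, with exact Poisson (χ²) limits. Results are stratified by
line of therapy.

## Worked example

```python
import hepatosafe as hs

dataset = hs.generate_worked_fixture()        # 20 handcrafted patients
config = hs.default_study_config()
report = hs.run_study(dataset, config)

print(f"cohort entries: {len(report.cohort)}, exclusions: {len(report.exclusions)}")
cell, = [c for c in report.incidence_cells
         if c.drug == "sorafenib" and c.category == "Possible Hy's law"
         and c.stratum == "overall"]
print(f"sorafenib Hy's law: {cell.n_cases}/{cell.n_evaluated}, "
      f"cum inc {cell.cum_inc_pct}% {cell.cum_inc_ci}")
print(hs.cumulative_incidence(7, 151), hs.exact_binomial_ci(7, 151))
```

prints

```
cohort entries: 19, exclusions: 4
sorafenib Hy's law: 1/3, cum inc 33.3% (0.8, 90.6)
4.6 (1.9, 9.3)
```

The fixture's 23 candidate (patient, drug) pairs yield 19 cohort entries;
the 4 exclusions carry reason codes (missing baseline lab, age < 18,
concurrent anti-VEGF use). The one built-in same-day Hy's-law triple is
found among the three evaluable sorafenib users, and 7 events among 151
evaluated patients correspond to a cumulative incidence of 4.6%
(95% CI 1.9–9.3).

The same pipeline runs from the shell:

```sh
hepatosafe synth --out data/ --seed 1          # synthetic four-table EMR
hepatosafe run --data data/ --out report/      # full analysis, CSV + markdown
```

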