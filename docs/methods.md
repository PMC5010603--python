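# Methods

This note documents the analytic conventions the package implements,
the choices made where more than one convention is defensible, and what
the synthetic generator does and does not emulate.

## Data model

The pipeline consumes four flat CSV tables — patients, diagnoses, drug
records, lab results — at day resolution. The upper limit of normal
(ULN) is carried on every lab row rather than in a site-level reference
table: surveillance data pooled across health systems mixes assays with
different reference ranges, and the per-row representation needs no
external lookup. ICD-9 codes are stored dotted; a code-list entry
without a dot ("570") matches itself and dotted children ("570.1") but
not "5701", and a dotted entry ("189.0") matches itself and fifth-digit
children. Validation is total: every malformed row is reported with its
table name and row index, and foreign keys must resolve.

## Exposure and episodes

Each drug record covers an inclusive interval starting on its date. The
duration is the recorded days-supply when present, otherwise an imputed
default per drug: 30 days for pazopanib and sorafenib prescriptions, 28
days for sunitinib (its 4-weeks-on cycle), and 14 days per bevacizumab
administration (the indicated infusion interval). Intervals merge into
one treatment episode when the uncovered gap between them — counted
exclusive of both endpoints, so an interval ending day *e* and the next
starting day *s* have gap *s − e − 1* — is at most 30 days; a longer gap
ends one episode and starts the next. Episode spans therefore include
bridged short gaps, and person-time is the inclusive span day count;
this matches the convention that a continuous course of therapy,
including refill slack, is at-risk time.

An alternate RCC treatment starting at *t*, with no index-drug record on
or after *t*, truncates the current episode at *t − 1* and ends episode
building; an alternate start on the index start date itself is handled
upstream by the concurrent-use exclusion. The builder is property-tested
against a brute-force day-bitmap oracle (mark covered days, clear
everything from the truncation day, extract maximal runs tolerating
≤ 30 unmarked days).

## Cohort entry

Entry requires: start inside the accrual window (2009-10-01 to
2013-02-17 by default); an RCC diagnosis (189.0/189.1) on or before
start; age ≥ 18 at start; at least one ALT and one bilirubin result in
the inclusive baseline window [start − 30 d, start]; and no other
anti-VEGF episode covering the start date. Exclusions are logged with
reason codes, checked in that order, so stage accounting always
balances. "New user" means no earlier same-drug record anywhere in the
dataset; with no minimum enrollment requirement, prior use outside the
data is undetectable and is a documented limitation rather than a
testable criterion.

Line of therapy is 1 plus the number of distinct prior regimens, where
antineoplastic drugs whose first starts fall within 30 days of one
another count as one regimen (combination therapy). The grouping window
and the antineoplastic drug list are configuration, not science: the
source conventions for line numbering are under-specified, so the
constant is exposed (`regimen_window_days`, default 30). Metastasis
sites come from ICD-9 196–198 codes on or before start via a
configurable map (lung 197.0, liver 197.7, bone/marrow 198.5,
brain/spinal cord 198.3–198.4, adrenal 198.7; other 196–198 codes →
"other").

## Outcomes

Lab results are analysed as multiples of their own ULN. The category
catalog is fixed: ALT-or-AST bands ≥3x–4.99x and ≥5x–9.99x plus open
thresholds ≥2x, ≥3x, ≥5x, ≥8x, ≥10x; ALP >1x, >2x, >3x, ≥2x–2.99x,
≥3x–4.99x, ≥5x; bilirubin >1x, ≥1.5x–1.99x, ≥2x–4.99x, ≥2x, ≥5x.
Printed band upper limits like "4.99x" are implemented as half-open
intervals ([3, 5)): a 6.0x result is an event for ≥5x–9.99x but not for
≥3x–4.99x. "ALT or AST" takes the daily maximum of the two multiples.

Baseline is summarized as the maximum multiple in the baseline window —
the conservative choice for eligibility, since any baseline result at or
above a category's lower threshold (strictly above, for >-type bounds)
removes the patient from that category's numerator and denominator.
Labs dated on the start date are baseline only; follow-up begins the day
after. Elevation detection is restricted to labs dated inside exposure
episodes of the index drug — results in >30-day treatment gaps do not
qualify — and by default events in any episode count, consistent with
summing person-time across separate periods of exposure
(`first_episode_only` restricts to the first episode).

The Hy's-law laboratory signal requires ALT or AST ≥3x, bilirubin ≥2x
and ALP <2x evaluated on the same calendar day; if ALP is unmeasured
that day the combination cannot be verified and is not satisfied. Both
choices are configurable (`hys_law_window_days` widens the concurrency
window; `alp_required=False` treats missing ALP as passing). The DILI
screen intentionally differs: it uses ALT only with strict inequalities
(ALT >3x with bilirubin >2x on the same day), adds the ICD-9 code list
277.4, 570.x, 572.8, 573.3, 573.8, 576.8, 782.4, and runs over the
earliest-to-latest any-anti-VEGF exposure span plus 90 days. Final DILI
status is an adjudicated, human determination and is accepted as an
external input, never computed.

## Statistics

Cumulative incidence is cases over patients evaluated, in percent.
Confidence limits are exact Clopper–Pearson (beta quantiles); this
choice reproduces published-style cells (7/151 → 4.6 (1.9, 9.3);
6/203 → 3.0 (1.1, 6.3)) where Wilson limits do not. Zero-case cells
carry the exact one-sided 97.5% upper bound 100·(1 − 0.025^(1/n)),
which is identical to the two-sided 95% Clopper–Pearson upper limit at
zero cases (an identity the tests assert).

Person-time sums inclusive episode day counts, divided by 365.25,
censored at the first qualifying elevation for the category at hand —
the event day is counted, and episodes beginning after the event
contribute nothing. Rates are cases per 100 person-years with exact
Poisson limits from χ² quantiles (lower χ²(α/2, 2k)/2, upper
χ²(1−α/2, 2k+2)/2) scaled by person-time. Percentages and rates are
rounded half-up to one decimal, as tables print them; cells with an
empty denominator render as a marker (`n/a`), never as zero. Incidence
cells are produced overall and stratified by line of therapy (first
line vs second or higher); time-to-event summaries (mean and median
days from drug start) are reported for ALT/AST ≥3x, bilirubin ≥2x and
the Hy's-law combination, with `NA` when no events occurred.

## Synthetic generator

The generator emulates the structure the analysis assumes, with every
patient cohort-eligible by construction: RCC code before start, baseline
ALT and bilirubin inside the window, age 40–85. Exposure is a refill
chain of imputed-duration records with Poisson-distributed extra gap
days (mean 3 by default, so courses stay continuous); follow-up labs
arrive every `lab_interval_days` (default 30) while exposed.

Elevations are realized event-time-first: a latent crossing time is
drawn from a constant per-(drug, analyte) hazard (exponential, clock at
drug start), and the qualifying value is placed at the next scheduled
visit at or after that time. Detection is therefore
measurement-limited, which is the attenuation mechanism routine-care
surveillance actually faces: a 7-day schedule recovers a 0.30/py hazard
as a rate near 30 per 100 person-years, while a 90-day schedule loses
late events and inflates time-to-detection, biasing the estimate low.
Between events, values are i.i.d. log-normal on the multiple scale
(median 0.6x ULN, σ = 0.25), capped below 2x ULN so a zero-hazard run
produces no threshold crossings at 2x or above. A configurable fraction
of ALT/AST events co-occur with bilirubin ≥2x and ALP <2x on the
detection day (Hy's-law triples); optional switching to an alternate
anti-VEGF and a DILI-code hazard exercise truncation and the screen.

The generator does **not** emulate: within-patient lab autocorrelation,
dose titration or adherence, informative censoring (toxicity-driven
discontinuation), comorbidity structure, or realistic demographic
margins. Passing tests therefore demonstrate that the analysis code
implements its stated conventions correctly and recovers known
parameters under its own assumptions — not that those assumptions hold
in any particular health system's data.

## Problem sizes and numerics

The parameter-recovery experiments use 2,000 patients per arm, giving
roughly 500 events at a 0.30/py hazard over one year and a Monte-Carlo
standard error near 1.3 per 100 person-years; recovery is asserted
within three such standard errors. The episode oracle comparison runs
1,000 random interval sets over a 400-day horizon; interval-coverage
simulation uses 10,000 binomial replicates at n = 150, p = 0.05. Dates
are `datetime.date` end to end; no floating-point time arithmetic is
involved, and ties (same-day labs) resolve by taking the daily maximum
multiple per analyte.

## Known limitations

Exposure imputed from order dates is imprecise; events outside the
captured lab stream are invisible; the alternate-treatment truncation
rule cannot distinguish combination therapy from switching when records
interleave; and line-of-therapy numbering depends on a configurable
grouping convention. Printed zero-case bounds in the surveillance
literature do not always match the exact formula; this package always
uses the stated definition.
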