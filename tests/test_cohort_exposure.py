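import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepatosafe.cohort_exposure import (
    assign_exposure_interval,
    build_treatment_episodes,
    derive_concomitant_meds,
    derive_line_of_therapy,
    derive_metastases,
    select_new_users,
)
from hepatosafe.cohort_exposure import Episode

from .conftest import day


def oracle_episodes(intervals, alternates=(), gap_days=30, horizon=600):
    """Brute-force day-bitmap reference for episode construction.

    Marks covered days, clears everything at/after the first alternate
    start not followed by an index record, then extracts maximal runs of
    covered days allowing unmarked stretches of at most ``gap_days``.
    """
    covered = [False] * horizon
    for s, e in intervals:
        for d in range(s, e + 1):
            covered[d] = True
    starts = [s for s, _ in intervals]
    cutoff = truncator = None
    for drug, t in sorted(alternates, key=lambda x: x[1]):
        if not any(s >= t for s in starts):
            cutoff, truncator = t, drug
            break
    if cutoff is not None:
        for d in range(max(cutoff, 0), horizon):
            covered[d] = False
    days = [d for d in range(horizon) if covered[d]]
    if not days:
        return []
    runs = []
    run_start = prev = days[0]
    for d in days[1:]:
        if d - prev - 1 > gap_days:
            runs.append((run_start, prev, None))
            run_start = d
        prev = d
    runs.append((run_start, prev, None))
    if cutoff is not None and runs and runs[-1][1] == cutoff - 1:
        runs[-1] = (runs[-1][0], runs[-1][1], truncator)
    return runs


def as_tuples(episodes):
    base = day(0)
    return [
        ((ep.start - base).days, (ep.end - base).days, ep.truncated_by) for ep in episodes
    ]


def dated(intervals):
    return [(day(s), day(e)) for s, e in intervals]


class TestAssignExposureInterval:
    @pytest.mark.parametrize(
        "drug,start,supply,expected_end",
        [
            ("pazopanib", 100, None, 129),  # imputed 30-day oral course
            ("sorafenib", 100, None, 129),
            ("sunitinib", 0, None, 27),  # 4-weeks-on cycle
            ("bevacizumab", 50, None, 63),  # 14-day infusion interval
            ("pazopanib", 10, 90, 99),  # recorded days-supply honored
        ],
    )
    def test_durations(self, study_config, drug, start, supply, expected_end):
        s, e = assign_exposure_interval(drug, day(start), supply, study_config)
        assert (s, e) == (day(start), day(expected_end))

    def test_unknown_drug_is_a_configuration_error(self, study_config):
        with pytest.raises(KeyError, match="axitinib"):
            assign_exposure_interval("axitinib", day(0), None, study_config)


class TestBuildTreatmentEpisodes:
    def test_gap_of_5_days_merges(self):
        eps = build_treatment_episodes(dated([(0, 29), (35, 64)]))
        assert as_tuples(eps) == [(0, 64, None)]

    def test_gap_of_exactly_30_days_merges(self):
        eps = build_treatment_episodes(dated([(0, 29), (60, 89)]))
        assert as_tuples(eps) == [(0, 89, None)]

    def test_gap_of_31_days_splits(self):
        eps = build_treatment_episodes(dated([(0, 29), (61, 90)]))
        assert as_tuples(eps) == [(0, 29, None), (61, 90, None)]

    def test_gap_of_40_days_splits(self):
        eps = build_treatment_episodes(dated([(0, 29), (70, 99)]))
        assert as_tuples(eps) == [(0, 29, None), (70, 99, None)]

    def test_overlapping_intervals_merge(self):
        eps = build_treatment_episodes(dated([(0, 29), (20, 49)]))
        assert as_tuples(eps) == [(0, 49, None)]

    def test_alternate_drug_truncates_to_day_before(self):
        eps = build_treatment_episodes(
            dated([(0, 29)]), alternate_starts=[("sunitinib", day(15))]
        )
        assert as_tuples(eps) == [(0, 14, "sunitinib")]

    def test_alternate_followed_by_index_record_does_not_truncate(self):
        eps = build_treatment_episodes(
            dated([(0, 29), (35, 64)]), alternate_starts=[("sunitinib", day(15))]
        )
        assert as_tuples(eps) == [(0, 64, None)]

    def test_unsorted_intervals_are_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            build_treatment_episodes(dated([(40, 50), (0, 29)]))


interval_sets = st.lists(
    st.tuples(st.integers(0, 400), st.integers(0, 60)).map(lambda t: (t[0], t[0] + t[1])),
    min_size=1,
    max_size=10,
).map(sorted)
alternate_sets = st.lists(
    st.tuples(st.sampled_from(["sunitinib", "sorafenib"]), st.integers(0, 470)),
    max_size=3,
)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(intervals=interval_sets, alternates=alternate_sets)
def test_episode_builder_matches_bitmap_oracle(intervals, alternates):
    dated_alts = [(d, day(t)) for d, t in alternates]
    got = as_tuples(build_treatment_episodes(dated(intervals), dated_alts))
    assert got == oracle_episodes(intervals, alternates)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(intervals=interval_sets)
def test_exposure_day_conservation(intervals):
    """Episode spans cover every interval day; without bridged gaps or
    overlap the episode day count equals the interval day count."""
    eps = build_treatment_episodes(dated(intervals))
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e + 1))
    base = day(0)
    span_days = set()
    for ep in eps:
        span_days.update(range((ep.start - base).days, (ep.end - base).days + 1))
    assert covered <= span_days
    assert len(span_days) >= len(covered)
    if span_days == covered:
        assert sum(ep.n_days for ep in eps) == len(covered)


class TestLineOfTherapy:
    def test_no_prior_treatment_is_first_line(self):
        assert derive_line_of_therapy([], day(100)) == 1

    def test_one_prior_course_is_second_line(self):
        assert derive_line_of_therapy([("sunitinib", day(0)), ("sunitinib", day(28))],
                                      day(100)) == 2

    def test_two_separated_prior_regimens_are_third_line(self):
        prior = [("interferon", day(0)), ("sunitinib", day(120))]
        assert derive_line_of_therapy(prior, day(300)) == 3

    def test_co_started_drugs_form_one_regimen(self):
        prior = [("interferon", day(0)), ("interleukin-2", day(10))]
        assert derive_line_of_therapy(prior, day(300)) == 2

    def test_prior_date_after_start_is_rejected(self):
        with pytest.raises(ValueError):
            derive_line_of_therapy([("sunitinib", day(10))], day(5))


class TestMetastases:
    def make_dx(self, codes, on=0):
        import pandas as pd

        return pd.DataFrame(
            [("P", day(on), c) for c in codes], columns=["patient_id", "date", "icd9"]
        )

    def test_lung_code(self, study_config):
        assert derive_metastases(self.make_dx(["197.0"]), day(10), study_config) == {"lung"}

    def test_bone_code(self, study_config):
        assert derive_metastases(self.make_dx(["198.5"]), day(10), study_config) == {
            "bone_or_marrow"
        }

    def test_unmapped_secondary_code_is_other(self, study_config):
        assert derive_metastases(self.make_dx(["196.2"]), day(10), study_config) == {"other"}

    def test_no_codes_is_none(self, study_config):
        assert derive_metastases(self.make_dx(["189.0"]), day(10), study_config) == {"none"}

    def test_codes_after_start_are_ignored(self, study_config):
        assert derive_metastases(self.make_dx(["197.0"], on=20), day(10), study_config) == {
            "none"
        }


class TestConcomitantMeds:
    def make_rx(self, rows):
        import pandas as pd

        return pd.DataFrame(
            [("P", drug, day(d), None, "prescription") for drug, d in rows],
            columns=["patient_id", "drug", "date", "days_supply", "kind"],
        )

    def episodes(self):
        return [Episode("P", "pazopanib", day(100), day(160)),
                Episode("P", "pazopanib", day(200), day(260))]

    def test_record_10_days_before_start_included(self):
        rx = self.make_rx([("simvastatin", 90), ("pazopanib", 100)])
        meds = derive_concomitant_meds(rx, self.episodes(), day(100), "pazopanib")
        assert meds == {"simvastatin"}

    def test_record_inside_second_episode_included(self):
        rx = self.make_rx([("amoxicillin", 230), ("pazopanib", 100)])
        meds = derive_concomitant_meds(rx, self.episodes(), day(100), "pazopanib")
        assert meds == {"amoxicillin"}

    def test_record_31_days_before_start_excluded(self):
        rx = self.make_rx([("warfarin", 69), ("pazopanib", 100)])
        meds = derive_concomitant_meds(rx, self.episodes(), day(100), "pazopanib")
        assert meds == frozenset()


class TestSelectNewUsers:
    def test_fixture_inclusions_and_exclusion_reasons(self, fixture_dataset, study_config):
        entries, exclusions = select_new_users(fixture_dataset, study_config)
        included = {(e.patient_id, e.drug) for e in entries}
        assert ("F01", "pazopanib") in included
        reasons = {(x.patient_id, x.drug): x.reason for x in exclusions}
        assert reasons[("F09", "pazopanib")] == "missing_baseline_lab"
        assert reasons[("F10", "sunitinib")] == "age"
        assert reasons[("F03", "sunitinib")] == "concurrent_anti_vegf"

    def test_no_entry_has_an_earlier_same_drug_record(self, fixture_dataset, study_config):
        entries, _ = select_new_users(fixture_dataset, study_config)
        rx = fixture_dataset.drug_records
        for e in entries:
            mine = rx[(rx["patient_id"] == e.patient_id) & (rx["drug"] == e.drug)]
            assert min(mine["date"]) == e.start_date

    def test_patient_can_enter_under_two_drugs_at_different_times(
        self, fixture_dataset, study_config
    ):
        entries, _ = select_new_users(fixture_dataset, study_config)
        f15 = sorted((e.drug for e in entries if e.patient_id == "F15"))
        assert f15 == ["pazopanib", "sunitinib"]
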