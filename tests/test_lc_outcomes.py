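import datetime

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepatosafe.cohort_exposure import Episode
from hepatosafe.lc_outcomes import (
    baseline_multiple,
    category_eligibility,
    default_catalog,
    detect_first_elevation,
    detect_hys_law,
    hys_law_combination,
    screen_dili,
    uln_multiple,
)

from .conftest import day


def labs_frame(rows):
    """rows: (day, analyte, multiple); ULN fixed at 40 for simplicity."""
    return pd.DataFrame(
        [("P", day(d), a, m * 40.0, 40.0) for d, a, m in rows],
        columns=["patient_id", "date", "analyte", "value", "uln"],
    )


EPISODES = [Episode("P", "pazopanib", day(0), day(180))]


@pytest.fixture(scope="module")
def by_label():
    return {c.label: c for c in default_catalog()}


def test_uln_multiple_is_value_over_uln():
    assert uln_multiple(80.0, 40.0) == 2.0
    assert uln_multiple(0.0, 40.0) == 0.0
    with pytest.raises(ValueError):
        uln_multiple(80.0, 0.0)


class TestBaselineMultiple:
    def test_maximum_over_window(self):
        labs = labs_frame([(-20, "ALT", 1.2), (-5, "ALT", 2.1)])
        assert baseline_multiple(labs, "ALT", day(0)) == pytest.approx(2.1)

    def test_start_date_result_counts_as_baseline(self):
        labs = labs_frame([(0, "ALT", 1.4)])
        assert baseline_multiple(labs, "ALT", day(0)) == pytest.approx(1.4)

    def test_no_results_in_window_is_absent(self):
        labs = labs_frame([(-40, "ALT", 1.2), (5, "ALT", 1.2)])
        assert baseline_multiple(labs, "ALT", day(0)) is None

    def test_alt_or_ast_takes_either_analyte(self):
        labs = labs_frame([(-5, "AST", 3.2), (-5, "ALT", 1.0)])
        assert baseline_multiple(labs, "ALT_or_AST", day(0)) == pytest.approx(3.2)


class TestCategoryEligibility:
    def test_baseline_3x_blocks_categories_with_lower_at_or_below_3(self, by_label):
        for label in ("ALT/AST >=3x-4.99x", "ALT/AST >=2x", "ALT/AST >=3x"):
            assert not category_eligibility(3.0, by_label[label])

    def test_baseline_3x_keeps_higher_categories(self, by_label):
        for label in ("ALT/AST >=5x-9.99x", "ALT/AST >=5x", "ALT/AST >=8x", "ALT/AST >=10x"):
            assert category_eligibility(3.0, by_label[label])

    def test_absent_baseline_is_eligible(self, by_label):
        assert category_eligibility(None, by_label["ALT/AST >=2x"])

    def test_strict_lower_bound_admits_exact_baseline(self, by_label):
        # ALP >2x has an exclusive lower bound: a 2.0x baseline does not meet it
        assert category_eligibility(2.0, by_label["ALP >2x"])
        assert not category_eligibility(2.0, by_label["ALP >1x"])

    def test_monotone_eligibility_across_the_catalog(self):
        """Ineligibility at lower bound L implies ineligibility for every
        same-analyte category with an equal-or-lower bound of the same type."""
        catalog = default_catalog()
        for v in (1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 10.0, 12.0):
            for a in ("ALT_or_AST", "ALP", "BILI"):
                cats = [c for c in catalog if c.analyte == a]
                for c1 in cats:
                    for c2 in cats:
                        if (
                            c2.lower <= c1.lower
                            and c2.lower_inclusive == c1.lower_inclusive
                            and not category_eligibility(v, c1)
                        ):
                            assert not category_eligibility(v, c2)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(v=st.floats(min_value=0.0, max_value=15.0, allow_nan=False))
def test_band_membership_matches_explicit_range_arithmetic(v):
    for cat in default_catalog():
        lo_ok = v >= cat.lower if cat.lower_inclusive else v > cat.lower
        hi_ok = True
        if cat.upper is not None:
            hi_ok = v <= cat.upper if cat.upper_inclusive else v < cat.upper
        assert cat.contains(v) == (lo_ok and hi_ok)


class TestDetectFirstElevation:
    def test_event_with_days_to_event(self, by_label):
        labs = labs_frame([(-5, "ALT", 0.6), (30, "ALT", 3.5)])
        ev = detect_first_elevation(labs, by_label["ALT/AST >=3x"], EPISODES, day(0))
        assert ev is not None
        assert ev.days_to_event == 30
        assert ev.multiple == pytest.approx(3.5)

    def test_banded_category_excludes_values_above_the_band(self, by_label):
        labs = labs_frame([(30, "ALT", 6.0)])
        assert detect_first_elevation(labs, by_label["ALT/AST >=3x-4.99x"], EPISODES, day(0)) is None
        assert detect_first_elevation(labs, by_label["ALT/AST >=5x-9.99x"], EPISODES, day(0)) is not None

    def test_lab_on_start_date_is_baseline_not_follow_up(self, by_label):
        labs = labs_frame([(0, "ALT", 3.5)])
        assert detect_first_elevation(labs, by_label["ALT/AST >=3x"], EPISODES, day(0)) is None

    def test_lab_in_treatment_gap_does_not_qualify(self, by_label):
        episodes = [
            Episode("P", "sunitinib", day(0), day(27)),
            Episode("P", "sunitinib", day(70), day(97)),
        ]
        labs = labs_frame([(45, "ALT", 3.5)])
        assert detect_first_elevation(labs, by_label["ALT/AST >=3x"], episodes, day(0)) is None

    def test_first_episode_only_restriction(self, by_label):
        episodes = [
            Episode("P", "sunitinib", day(0), day(27)),
            Episode("P", "sunitinib", day(70), day(97)),
        ]
        labs = labs_frame([(80, "ALT", 3.5)])
        assert (
            detect_first_elevation(
                labs, by_label["ALT/AST >=3x"], episodes, day(0), first_episode_only=True
            )
            is None
        )
        assert (
            detect_first_elevation(labs, by_label["ALT/AST >=3x"], episodes, day(0)) is not None
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(-30, 200), st.floats(0.1, 12.0)),
            min_size=1,
            max_size=15,
        )
    )
    def test_returns_chronologically_first_qualifying_lab(self, rows):
        catalog = {c.label: c for c in default_catalog()}
        cat = catalog["ALT/AST >=3x"]
        labs = labs_frame([(d, "ALT", m) for d, m in rows])
        ev = detect_first_elevation(labs, cat, EPISODES, day(0))
        qualifying = sorted(
            d for d, m in rows if 0 < d <= 180 and cat.contains(max(
                mm for dd, mm in rows if dd == d))
        )
        if ev is None:
            assert not qualifying
        else:
            assert (ev.event_date - day(0)).days == qualifying[0]


class TestHysLaw:
    def test_same_day_triple_detected(self):
        labs = labs_frame([(20, "ALT", 3.5), (20, "BILI", 2.2), (20, "ALP", 1.5)])
        ev = detect_hys_law(labs, EPISODES, day(0))
        assert ev is not None and ev.event_date == day(20)

    def test_alp_exactly_2x_rejects_the_combination(self):
        labs = labs_frame([(20, "ALT", 3.5), (20, "BILI", 2.2), (20, "ALP", 2.0)])
        assert detect_hys_law(labs, EPISODES, day(0)) is None

    def test_split_days_fail_under_same_day_rule(self):
        labs = labs_frame([(10, "ALT", 3.5), (10, "ALP", 1.0), (12, "BILI", 2.2)])
        assert detect_hys_law(labs, EPISODES, day(0)) is None

    def test_split_days_pass_with_a_concurrency_window(self):
        labs = labs_frame([(10, "ALT", 3.5), (10, "ALP", 1.0), (12, "BILI", 2.2)])
        assert detect_hys_law(labs, EPISODES, day(0), window_days=2) is not None

    def test_unmeasured_alp_blocks_unless_not_required(self):
        labs = labs_frame([(20, "ALT", 3.5), (20, "BILI", 2.2)])
        assert detect_hys_law(labs, EPISODES, day(0)) is None
        assert detect_hys_law(labs, EPISODES, day(0), alp_required=False) is not None

    def test_combination_predicate_edges(self):
        assert hys_law_combination(3.0, 2.0, 1.99)
        assert not hys_law_combination(2.99, 2.0, 1.0)
        assert not hys_law_combination(3.0, 1.99, 1.0)

    def test_hys_event_implies_simultaneous_component_elevations(self):
        labs = labs_frame([(20, "AST", 4.0), (20, "BILI", 2.5), (20, "ALP", 0.9)])
        catalog = {c.label: c for c in default_catalog()}
        hys = detect_hys_law(labs, EPISODES, day(0))
        aa = detect_first_elevation(labs, catalog["ALT/AST >=3x"], EPISODES, day(0))
        bili = detect_first_elevation(labs, catalog["BILI >=2x"], EPISODES, day(0))
        assert hys is not None
        assert aa is not None and aa.event_date == hys.event_date
        assert bili is not None and bili.event_date == hys.event_date


class TestDILIScreen:
    DILI_CODES = ("277.4", "570", "572.8", "573.3", "573.8", "576.8", "782.4")

    def dx_frame(self, rows):
        return pd.DataFrame(
            [("P", day(d), c) for d, c in rows], columns=["patient_id", "date", "icd9"]
        )

    def test_570_child_code_prefix_matches_inside_span(self):
        flags = screen_dili(
            self.dx_frame([(50, "570.1")]), labs_frame([]), day(0), day(100), self.DILI_CODES
        )
        assert [f.trigger for f in flags] == ["icd9_code"]
        assert flags[0].detail == "570.1"

    def test_same_day_alt_and_bili_combination_flagged(self):
        labs = labs_frame([(50, "ALT", 3.2), (50, "BILI", 2.1)])
        flags = screen_dili(self.dx_frame([]), labs, day(0), day(100), self.DILI_CODES)
        assert [f.trigger for f in flags] == ["lab_combination"]

    def test_strict_inequalities_for_the_lab_combination(self):
        labs = labs_frame([(50, "ALT", 3.0), (50, "BILI", 2.1)])
        assert not screen_dili(self.dx_frame([]), labs, day(0), day(100), self.DILI_CODES)

    def test_code_at_span_end_plus_90_is_inside_window(self):
        flags = screen_dili(
            self.dx_frame([(190, "573.3")]), labs_frame([]), day(0), day(100), self.DILI_CODES
        )
        assert len(flags) == 1

    def test_code_at_span_end_plus_91_is_outside_window(self):
        flags = screen_dili(
            self.dx_frame([(191, "573.3")]), labs_frame([]), day(0), day(100), self.DILI_CODES
        )
        assert not flags
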