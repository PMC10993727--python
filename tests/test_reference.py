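import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoscreen.cohort import generate_cohort
from neoscreen.reference import (
    NEGATIVE,
    POSITIVE,
    ReferenceInterval,
    estimate_intervals,
    estimate_reference_interval,
    outcomes_to_frame,
    run_two_tier,
    screen_panel,
    screen_record,
)


def oracle_interval(values, lower_pct=0.5, upper_pct=99.5):
    """Independent sort-and-interpolate rank estimator: r = p/100·(n+1),
    clamped to [1, n], linear interpolation between order statistics."""
    s = sorted(values)
    n = len(s)

    def at(pct):
        r = min(max(pct / 100 * (n + 1), 1.0), float(n))
        i = int(math.floor(r))
        frac = r - i
        lo = s[i - 1]
        hi = s[min(i, n - 1)]
        return lo + frac * (hi - lo)

    return at(lower_pct), at(upper_pct)


class TestIntervalEstimator:
    def test_rank_interpolation_on_1_to_1000(self):
        iv = estimate_reference_interval(np.arange(1, 1001), analyte="x")
        assert iv.lower == pytest.approx(5.005)
        assert iv.upper == pytest.approx(995.995)

    def test_constant_vector_degenerates(self):
        with pytest.warns(UserWarning):
            iv = estimate_reference_interval([7.0] * 10, analyte="x")
        assert iv.lower == iv.upper == 7.0
        assert not iv.reliable

    def test_matches_oracle_for_all_sizes_up_to_50(self):
        rng = np.random.default_rng(1234)
        for n in range(1, 51):
            values = rng.lognormal(1.0, 0.7, size=n)
            with pytest.warns(UserWarning):
                iv = estimate_reference_interval(values, analyte="x")
            lo, hi = oracle_interval(values)
            assert iv.lower == pytest.approx(lo, abs=1e-12)
            assert iv.upper == pytest.approx(hi, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=1, max_size=50
        ),
        pcts=st.tuples(
            st.floats(min_value=0.1, max_value=49), st.floats(min_value=51, max_value=99.9)
        ),
    )
    def test_estimator_equals_oracle_property(self, values, pcts):
        lower_pct, upper_pct = pcts
        with pytest.warns(UserWarning):
            iv = estimate_reference_interval(values, lower_pct, upper_pct, analyte="x")
        lo, hi = oracle_interval(values, lower_pct, upper_pct)
        assert iv.lower == pytest.approx(lo, abs=1e-9, rel=1e-9)
        assert iv.upper == pytest.approx(hi, abs=1e-9, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_reference_interval([])


@pytest.fixture(scope="module")
def intervals(small_cohort):
    return estimate_intervals(small_cohort)


class TestScreening:
    def test_midpoint_panel_is_negative(self, intervals, registry, small_cohort):
        record = next(small_cohort.records())
        panel = {a: (iv.lower + iv.upper) / 2 for a, iv in intervals.items()}
        record = type(record)(
            id="mid", covariates=record.covariates, panel=panel,
            truth_disease=None, truth_zygosity="unaffected",
        )
        result, flags = screen_record(record, intervals, registry)
        assert result == NEGATIVE and flags == ()

    def test_high_phe_flags_both_phe_diseases(self, intervals, registry, small_cohort):
        record = next(small_cohort.records())
        panel = {a: (iv.lower + iv.upper) / 2 for a, iv in intervals.items()}
        panel["PHE"] = intervals["PHE"].upper * 1.5
        record = type(record)(
            id="hi-phe", covariates=record.covariates, panel=panel,
            truth_disease=None, truth_zygosity="unaffected",
        )
        result, flags = screen_record(record, intervals, registry)
        assert result == POSITIVE
        assert set(flags) == {"PAHD", "BH4D"}

    def test_low_c0_flags_carnitine_deficiency_only(self, intervals, registry, small_cohort):
        record = next(small_cohort.records())
        panel = {a: (iv.lower + iv.upper) / 2 for a, iv in intervals.items()}
        panel["C0"] = intervals["C0"].lower * 0.5
        record = type(record)(
            id="lo-c0", covariates=record.covariates, panel=panel,
            truth_disease=None, truth_zygosity="unaffected",
        )
        result, flags = screen_record(record, intervals, registry)
        assert result == POSITIVE
        assert set(flags) == {"PCD"}

    def test_widening_intervals_never_increases_flags(self, intervals, registry, small_cohort):
        panel = small_cohort.panel_matrix()
        base = screen_panel(panel, intervals, registry)["initial_positive"].sum()
        widened = {
            a: ReferenceInterval(a, iv.lower * 0.8, iv.upper * 1.2, iv.n_source)
            for a, iv in intervals.items()
        }
        wide = screen_panel(panel, widened, registry)["initial_positive"].sum()
        assert wide <= base


class TestTwoTier:
    def test_empty_cohort(self, registry, baselines):
        cohort = generate_cohort(0, registry, baselines, seed=0)
        intervals = {
            a: ReferenceInterval(a, 0.0, 1.0, 1000) for a in cohort.analytes
        }
        assert run_two_tier(cohort, intervals, registry, seed=0) == []

    def test_each_record_appears_exactly_once(self, small_cohort, registry):
        intervals = estimate_intervals(small_cohort)
        outcomes = run_two_tier(small_cohort, intervals, registry, seed=1)
        ids = [o.record_id for o in outcomes]
        assert ids == small_cohort.frame["id"].tolist()

    def test_perfect_retest_repeats_initial_flags(self, small_cohort, registry, baselines):
        intervals = estimate_intervals(small_cohort)
        outcomes = run_two_tier(
            small_cohort, intervals, registry,
            retest_correlation=1.0, seed=2, baselines=baselines,
        )
        frame = outcomes_to_frame(outcomes)
        recalled = frame[frame.recalled]
        assert (recalled.secondary_result == "suspected").all()

    def test_independent_retest_matches_false_positive_rate(self, registry, baselines):
        """With zero test-retest correlation the suspected fraction among
        recalled healthy subjects equals the initial false-positive rate."""
        cohort = generate_cohort(20_000, registry, baselines, seed=55, enrichment=0.0)
        intervals = estimate_intervals(cohort)
        outcomes = run_two_tier(
            cohort, intervals, registry,
            retest_correlation=0.0, seed=56, baselines=baselines,
        )
        frame = outcomes_to_frame(outcomes)
        initial_fpr = frame.recalled.mean()
        recalled = frame[frame.recalled]
        suspected_frac = (recalled.secondary_result == "suspected").mean()
        assert suspected_frac == pytest.approx(initial_fpr, abs=0.025)

    def test_recall_only_for_positives(self, small_cohort, registry):
        intervals = estimate_intervals(small_cohort)
        for o in run_two_tier(small_cohort, intervals, registry, seed=3):
            if o.recalled:
                assert o.initial_result == POSITIVE
            else:
                assert o.secondary_result == "not-applicable"
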