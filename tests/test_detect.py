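"""Baseline threshold estimation, labeling criteria, R_cs scoring and calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from capsip.detect import (
    BaselineStats,
    CapSipClassifier,
    LabelCall,
    OtuQuadruple,
    call_labels,
    compute_baseline,
    cumulative_rcs,
    evaluate_criteria,
    r_cs,
    read_calls_tsv,
    replication_filter,
    run_summary,
    write_calls_tsv,
)
from capsip.sip_tables import LibraryKey

from helpers import quad_table

percent = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)


def quad(ra, rb, rc, rd, otu="x", day=3.0):
    return OtuQuadruple(otu_id=otu, day=day, r_a=ra, r_b=rb, r_c=rc, r_d=rd)


class TestBaseline:
    def test_moments_against_numpy_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([0.8, 2.5, 2.6, 4.4])
        stats = compute_baseline(a, b, oxygen="oxic")
        diffs = a - b
        assert stats.mean_diff == pytest.approx(diffs.mean())
        assert stats.sd_diff == pytest.approx(diffs.std(ddof=1))
        assert stats.threshold_T == pytest.approx(diffs.mean() + 3 * diffs.std(ddof=1))
        assert stats.n_otus == 4

    def test_identical_columns_zero_threshold(self):
        a = np.array([10.0, 20.0, 70.0])
        stats = compute_baseline(a, a)
        assert stats.mean_diff == 0 and stats.sd_diff == 0 and stats.threshold_T == 0

    def test_absolute_mode(self):
        a = np.array([1.0, 2.0])
        b = np.array([2.0, 1.0])
        signed = compute_baseline(a, b, mode="signed")
        absolute = compute_baseline(a, b, mode="absolute")
        assert signed.mean_diff == pytest.approx(0.0)
        assert absolute.mean_diff == pytest.approx(1.0)
        assert absolute.sd_diff == pytest.approx(0.0)

    def test_fewer_than_two_otus_rejected(self):
        with pytest.raises(ValueError, match="2 OTUs"):
            compute_baseline(np.array([1.0]), np.array([2.0]))

    def test_threshold_identity_enforced(self):
        with pytest.raises(ValueError, match="mean_diff"):
            BaselineStats(oxygen="oxic", mean_diff=0.04, sd_diff=0.19, threshold_T=0.7)

    @given(
        diffs=st.lists(st.floats(min_value=-5, max_value=5, allow_nan=False),
                       min_size=2, max_size=40)
    )
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_threshold_identity_property(self, diffs):
        base = np.full(len(diffs), 50.0)
        stats = compute_baseline(base + np.asarray(diffs), base)
        assert stats.threshold_T == pytest.approx(stats.mean_diff + 3 * stats.sd_diff, abs=1e-9)


class TestRcsScore:
    @given(x=percent)
    @settings(derandomize=True, deadline=None)
    def test_equal_abundances_cancel(self, x):
        assert r_cs(quad(x, x, x, x)) == pytest.approx(0.0, abs=1e-12)

    @given(a=percent)
    @settings(derandomize=True, deadline=None)
    def test_reduces_to_ra_when_others_zero(self, a):
        assert r_cs(quad(a, 0, 0, 0)) == pytest.approx(a)

    def test_forced_arithmetic(self):
        assert r_cs(quad(12, 3, 3, 3)) == pytest.approx(9.0)
        assert r_cs(quad(9, 0, 0, 0)) == pytest.approx(9.0)

    @given(ra=percent, rb=percent, rc=percent, rd=percent,
           lam=st.floats(min_value=0.0, max_value=1.0))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_linearity_under_scaling(self, ra, rb, rc, rd, lam):
        full = r_cs(quad(ra, rb, rc, rd))
        scaled = r_cs(quad(lam * ra, lam * rb, lam * rc, lam * rd))
        assert scaled == pytest.approx(lam * full, abs=1e-9)


class TestCriteria:
    def test_all_criteria_met(self):
        call = evaluate_criteria(quad(5, 1, 1, 1), T=0.61)
        assert (call.c1, call.c2, call.c3, call.c4) == (True, True, True, True)
        assert call.r_cs == pytest.approx(4.0)
        assert call.labeled

    def test_c1_below_threshold_blocks_label(self):
        call = evaluate_criteria(quad(1.0, 0.5, 0.0, 0.0), T=0.61)
        assert not call.c1
        assert not call.labeled
        assert call.c2 and call.c3

    def test_tie_at_threshold_fails(self):
        call = evaluate_criteria(quad(1.0, 0.5, 0.0, 0.0), T=0.5)
        assert not call.c1  # R_a - R_b == T exactly: strict inequality
        assert not call.labeled

    def test_c4_can_pass_while_c1_to_c3_fail(self):
        # R_cs is the mean of the three margins: one large margin can push
        # it over T even when another margin fails.
        call = evaluate_criteria(quad(10.0, 0.0, 0.0, 9.5), T=1.0)
        assert call.c1 and call.c2 and not call.c3
        assert call.c4  # R_cs = (10 + 10 + 0.5)/3 ≈ 6.8 > 1
        assert not call.labeled

    @given(ra=percent, rb=percent, rc=percent, rd=percent,
           T=st.floats(min_value=0, max_value=10))
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_c4_is_mean_of_margins(self, ra, rb, rc, rd, T):
        """R_cs equals the mean of the three criterion margins, so criteria
        1-3 jointly imply criterion 4 and the strict mode never demotes."""
        call = evaluate_criteria(quad(ra, rb, rc, rd), T)
        margins = [ra - rb, ra - rc, ra - rd]
        assert call.r_cs == pytest.approx(np.mean(margins), abs=1e-9)
        if call.c1 and call.c2 and call.c3:
            assert call.c4
        strict = evaluate_criteria(quad(ra, rb, rc, rd), T, require_c4=True)
        assert strict.labeled == call.labeled

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            evaluate_criteria(quad(1, 0, 0, 0), T=-0.1)

    @given(ra=percent, rb=percent, rc=percent, rd=percent,
           bump=st.floats(min_value=0, max_value=50),
           T=st.floats(min_value=0, max_value=10))
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_monotone_in_ra(self, ra, rb, rc, rd, bump, T):
        """Raising R_a (all else fixed) never turns labeled off."""
        before = evaluate_criteria(quad(ra, rb, rc, rd), T)
        after = evaluate_criteria(quad(min(100.0, ra + bump), rb, rc, rd), T)
        if before.labeled:
            assert after.labeled


class TestEstimatorContract:
    def test_get_set_params_and_clone(self):
        est = CapSipClassifier(baseline_mode="absolute", require_c4=True)
        params = est.get_params()
        assert params["baseline_mode"] == "absolute" and params["require_c4"]
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_sets_suffixed_attributes(self):
        X = np.column_stack([[1.0, 2, 3, 4], [0.5, 2.2, 2.9, 4.6]])
        est = CapSipClassifier().fit(X)
        for attr in ("mean_diff_", "sd_diff_", "threshold_", "n_features_in_"):
            assert hasattr(est, attr)
        assert est.threshold_ == pytest.approx(est.mean_diff_ + 3 * est.sd_diff_)

    def test_predict_agrees_with_evaluate_criteria(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 10, size=(50, 4))
        T = 0.61
        est = CapSipClassifier(threshold=T)
        preds = est.predict(X)
        scores = est.decision_function(X)
        for i, row in enumerate(X):
            call = evaluate_criteria(quad(*row), T=T)
            assert preds[i] == call.labeled
            assert scores[i] == pytest.approx(call.r_cs)

    def test_unfitted_without_threshold_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            CapSipClassifier().predict(np.zeros((1, 4)))

    def test_input_validation(self):
        est = CapSipClassifier(threshold=1.0)
        with pytest.raises(ValueError, match=r"\(n, 4\)"):
            est.predict(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="n_otus, 2"):
            CapSipClassifier().fit(np.zeros((3, 4)))


class TestCallLabels:
    def test_dominant_otu_gets_max_rcs(self):
        quads = [(50.0, 0.5, 0.5, 0.5), (0.9, 0.8, 0.7, 0.6), (0.0, 0.0, 0.0, 0.0)]
        table = quad_table(quads)
        baseline = BaselineStats.from_moments(0.04, 0.19)
        calls = call_labels(table, baseline, t0=0.0)
        day3 = [c for c in calls if c.day == 3.0]
        assert day3[0].otu_id == "OTU_1"
        assert day3[0].labeled
        assert day3[0].r_cs == max(c.r_cs for c in day3)
        assert not any(c.labeled for c in day3[1:])

    def test_sorted_by_day_then_rcs_descending(self):
        table = quad_table([(5.0, 1.0, 1.0, 1.0), (9.0, 1.0, 1.0, 1.0)])
        calls = call_labels(table, BaselineStats.from_moments(0.0, 0.1), t0=0.0)
        days = [c.day for c in calls]
        assert days == sorted(days)
        scores = [c.r_cs for c in calls if c.day == 3.0]
        assert scores == sorted(scores, reverse=True)

    def test_missing_library_is_named(self):
        table = quad_table([(5.0, 1.0, 1.0, 1.0)])
        # drop the light-13C column
        df = table.values.drop(columns=[LibraryKey("13C", "oxic", 3.0, "light")])
        from capsip.sip_tables import AbundanceTable
        broken = AbundanceTable(df, "percent")
        with pytest.raises(KeyError, match=r"13C\|oxic\|3\|light"):
            call_labels(broken, BaselineStats.from_moments(0.04, 0.19), t0=0.0)

    def test_counts_table_rejected(self):
        from capsip.sip_tables import AbundanceTable
        table = quad_table([(5.0, 1.0, 1.0, 1.0)])
        counts = AbundanceTable(table.values * 10, "counts")
        with pytest.raises(ValueError, match="percent"):
            call_labels(counts, BaselineStats.from_moments(0.04, 0.19))

    def test_empty_day_set_gives_empty_calls(self):
        table = quad_table([(5.0, 1.0, 1.0, 1.0)])
        calls = call_labels(table, BaselineStats.from_moments(0.04, 0.19), t0=0.0, days=[])
        assert calls == []


def _mk_call(otu, day, labeled, rcs=1.0):
    return LabelCall(otu_id=otu, day=day, r_a=0, r_b=0, r_c=0, r_d=0,
                     c1=labeled, c2=labeled, c3=labeled, c4=labeled,
                     r_cs=rcs, labeled=labeled, threshold_used=0.61)


class TestReplicationFilter:
    def test_multi_day_labels_retained(self):
        calls = [_mk_call("a", 3, True), _mk_call("a", 10, True), _mk_call("b", 70, True)]
        out = replication_filter(calls, min_days=2)
        by = {(c.otu_id, c.day): c for c in out}
        assert by[("a", 3)].labeled and by[("a", 10)].labeled
        assert not by[("b", 70)].labeled
        assert "1 day" in by[("b", 70)].demoted_reason

    def test_min_days_one_is_identity(self):
        calls = [_mk_call("a", 3, True), _mk_call("b", 10, False)]
        assert replication_filter(calls, min_days=1) == calls

    def test_invalid_min_days(self):
        with pytest.raises(ValueError):
            replication_filter([], min_days=0)


class TestCumulativeRcs:
    def test_sums_labeled_only(self):
        calls = [_mk_call("a", 3, True, 4.0), _mk_call("b", 3, True, 5.0),
                 _mk_call("c", 3, False, 99.0)]
        assert cumulative_rcs(calls, 3) == pytest.approx(9.0)

    def test_no_labeled_is_zero(self):
        assert cumulative_rcs([_mk_call("a", 3, False)], 3) == 0.0

    def test_unevaluated_day_rejected(self):
        with pytest.raises(KeyError, match="10"):
            cumulative_rcs([_mk_call("a", 3, True)], 10)


class TestReporting:
    def test_calls_tsv_round_trip(self, tmp_path):
        calls = [_mk_call("a", 3, True, 4.0), _mk_call("b", 3, False, -0.5)]
        calls[1] = replication_filter(calls, min_days=2)[1]
        p = tmp_path / "calls.tsv"
        write_calls_tsv(calls, p)
        back = read_calls_tsv(p)
        assert [c.otu_id for c in back] == ["a", "b"]
        assert back[0].r_cs == pytest.approx(4.0)
        assert back[0].labeled and not back[1].labeled

    def test_run_summary_structure(self):
        calls = [_mk_call("a", 3, True, 4.0), _mk_call("a", 10, True, 2.0)]
        baseline = BaselineStats.from_moments(0.04, 0.19)
        s = run_summary(calls, baseline)
        assert s["baseline"]["threshold_T_percent"] == pytest.approx(0.61)
        assert s["days"]["3"]["cumulative_r_cs_percent"] == pytest.approx(4.0)
        assert s["days"]["10"]["n_labeled"] == 1
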