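"""Kaplan-Meier, logrank, minimal-p cutoffs and the OR-combination classifier."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from crcmark.errors import SchemaError
from crcmark.survival import (
    combine_markers_or,
    candidate_cutoffs,
    fit_panel_cutoffs,
    km_estimate,
    logrank_test,
    optimal_cutoff,
)


# ---------------------------------------------------------------- Kaplan-Meier
def test_km_all_censored_stays_at_one():
    curve = km_estimate([5, 10, 15], [False, False, False])
    assert curve.survival_at(0) == 1.0
    assert curve.survival_at(100) == 1.0
    assert len(curve.times) == 0


def test_km_no_censoring_is_empirical_survival():
    curve = km_estimate([1, 2, 3], [True, True, True])
    np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])


def test_km_hand_worked_product_limit():
    """5 subjects, censoring at an event time counted at risk at that time."""
    curve = km_estimate([2, 4, 4, 6, 9], [1, 1, 0, 1, 0])
    np.testing.assert_allclose(curve.times, [2, 4, 6])
    np.testing.assert_allclose(curve.survival, [0.8, 0.6, 0.3])
    np.testing.assert_array_equal(curve.at_risk, [5, 4, 2])
    assert curve.survival_at(5.0) == pytest.approx(0.6)


def test_km_invariant_under_row_permutation(rng):
    t = rng.exponential(50, 40)
    e = rng.random(40) < 0.6
    perm = rng.permutation(40)
    a, b = km_estimate(t, e), km_estimate(t[perm], e[perm])
    np.testing.assert_allclose(a.times, b.times)
    np.testing.assert_allclose(a.survival, b.survival)


# --------------------------------------------------------------------- logrank
def test_logrank_identical_groups_is_null():
    t = [3, 5, 8, 11]
    e = [1, 0, 1, 1]
    chi2, p = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_no_events_gives_zero_chi2():
    chi2, p = logrank_test([3, 5, 8], [0, 0, 0], ["a", "a", "b"])
    assert chi2 == 0.0
    assert p == 1.0


def test_logrank_hand_tabulated_example():
    """6-subject O/E/V tabulation: O1=3, E1=1.9, V=0.99 -> chi2 = 1.1^2/0.99."""
    t = [6, 13, 21, 10, 15, 30]
    e = [1, 1, 1, 1, 0, 1]
    g = ["A", "A", "A", "B", "B", "B"]
    chi2, p = logrank_test(t, e, g)
    assert chi2 == pytest.approx(1.1**2 / 0.99)
    assert p == pytest.approx(0.26892, abs=1e-4)


def test_logrank_symmetric_in_group_labels(rng):
    t = rng.exponential(30, 30)
    e = rng.random(30) < 0.7
    g = rng.random(30) < 0.4
    a = logrank_test(t, e, np.where(g, "x", "y"))
    b = logrank_test(t, e, np.where(g, "y", "x"))
    assert a[0] == pytest.approx(b[0])
    assert a[0] >= 0.0


def test_logrank_matches_lifelines(rng):
    for _ in range(10):
        n = 40
        t = rng.exponential(40, n)
        e = rng.random(n) < 0.7
        g = rng.random(n) < 0.5
        if g.all() or not g.any():
            continue
        chi2, p = logrank_test(t, e, g)
        ref = lifelines_logrank(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_requires_two_groups():
    with pytest.raises(ValueError):
        logrank_test([1, 2], [1, 1], ["a", "a"])


# -------------------------------------------------------------- optimal cutoff
def scan_oracle(values, times, events, min_group_fraction):
    """Exhaustive scan using the lifelines logrank as the independent engine."""
    v = np.asarray(values, float)
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    n = len(v)
    best = None
    for c in candidate_cutoffs(v):
        high = v > c
        if high.sum() < min_group_fraction * n or (~high).sum() < min_group_fraction * n:
            continue
        r = lifelines_logrank(t[~high], t[high], e[~high], e[high])
        key = (r.p_value, -r.test_statistic, c)
        if best is None or key < best[0]:
            best = (key, c, r.p_value)
    return best


def test_optimal_cutoff_matches_exhaustive_scan(rng):
    for n in (20, 60, 200):
        v = rng.lognormal(0, 1, n)
        t = rng.exponential(52 / (1 + v), n) + 0.5
        e = rng.random(n) < 0.8
        fit = optimal_cutoff(v, t, e, min_group_fraction=0.1)
        _, c_ref, p_ref = scan_oracle(v, t, e, 0.1)
        assert fit.cutoff == pytest.approx(c_ref)
        assert fit.p_value == pytest.approx(p_ref, rel=1e-9)


def test_optimal_cutoff_p_not_larger_than_any_admissible_candidate(rng):
    n = 50
    v = rng.lognormal(0, 1, n)
    t = rng.exponential(30, n)
    e = rng.random(n) < 0.7
    fit = optimal_cutoff(v, t, e, min_group_fraction=0.1)
    for c in candidate_cutoffs(v):
        high = v > c
        if high.sum() < 0.1 * n or (~high).sum() < 0.1 * n:
            continue
        _, p = logrank_test(t, e, high)
        assert fit.p_value <= p + 1e-12


def test_optimal_cutoff_separating_marker():
    """Marker splitting early deaths from long survivors: cutoff between clusters."""
    v = np.array([1, 1.2, 1.1, 0.9, 5.0, 5.5, 6.0, 5.2])
    t = np.array([100, 110, 120, 130, 5, 8, 6, 9], dtype=float)
    e = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
    fit = optimal_cutoff(v, t, e, min_group_fraction=0.2)
    assert 1.2 < fit.cutoff < 5.0
    assert fit.n_low == 4 and fit.n_high == 4


def test_optimal_cutoff_constant_marker_errors():
    with pytest.raises(ValueError):
        optimal_cutoff([2.0] * 5, [1, 2, 3, 4, 5], [1, 1, 1, 1, 1])


def test_minimal_p_selection_is_optimistic_under_null(rng):
    """With the marker independent of survival, the unadjusted minimal p
    rejects far more often than the nominal 5% — the known optimism of
    minimal-p cutpoint selection."""
    rejections = 0
    reps = 200
    for _ in range(reps):
        n = 40
        v = rng.lognormal(0, 1, n)
        t = rng.exponential(40, n)
        e = rng.random(n) < 0.8
        fit = optimal_cutoff(v, t, e, min_group_fraction=0.1)
        rejections += fit.p_value < 0.05
    assert rejections / reps > 0.15


# ---------------------------------------------------------------- combination
def test_combine_all_below_cutoffs_is_favorable():
    matrix = pd.DataFrame({"CEA": [1.0], "miR-21": [0.5]}, index=["P1"])
    (call,) = combine_markers_or(matrix, {"CEA": 5.0, "miR-21": 1.0})
    assert call.risk == "favorable"
    assert call.triggering_markers == ()


def test_combine_single_exceedance_triggers():
    matrix = pd.DataFrame({"CEA": [6.0], "miR-21": [0.5]}, index=["P1"])
    (call,) = combine_markers_or(matrix, {"CEA": 5.0, "miR-21": 1.0})
    assert call.risk == "unfavorable"
    assert call.triggering_markers == ("CEA",)


def test_combine_tie_at_cutoff_falls_low_and_missing_is_non_evaluable():
    matrix = pd.DataFrame(
        {"CEA": [5.0, np.nan], "miR-21": [1.0, 0.2]}, index=["P1", "P2"]
    )
    calls = combine_markers_or(matrix, {"CEA": 5.0, "miR-21": 1.0})
    assert calls[0].risk == "favorable"
    assert calls[1].risk == "non-evaluable"


def test_combine_missing_marker_column_raises():
    matrix = pd.DataFrame({"CEA": [1.0]}, index=["P1"])
    with pytest.raises(SchemaError):
        combine_markers_or(matrix, {"CEA": 1.0, "miR-21": 1.0})


def test_panel_fit_on_cohort(processed_levels):
    clinical, _, levels, _ = processed_levels
    fits, matrix, calls, (chi2, p) = fit_panel_cutoffs(levels, clinical)
    assert {f.marker for f in fits} == {"CEA", "CA19-9", "miR-20a", "miR-21", "miR-23a"}
    n_palliative = (clinical["surgery_type"] == "palliative").sum()
    for f in fits:
        assert min(f.n_low, f.n_high) >= 0.1 * n_palliative
        assert 0.0 <= f.p_value <= 1.0
    risks = {c.risk for c in calls}
    assert risks <= {"favorable", "unfavorable", "non-evaluable"}
    for c in calls:
        if c.risk == "unfavorable":
            assert len(c.triggering_markers) >= 1
        elif c.risk == "favorable":
            assert c.triggering_markers == ()
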