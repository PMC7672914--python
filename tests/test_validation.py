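"""Ps bins, confusion metrics, rank AUC, O/E calibration table, group tests."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisskit.validation import (
    AGE_GROUPS,
    PS_BINS,
    PsBinSummary,
    ValidationError,
    age_group_label,
    assign_ps_bin,
    auc_rank,
    classify_survival,
    compare_groups,
    confusion_metrics,
    descriptive_table,
    percent,
    ps_bin_table,
    stratified_report,
)


# ---------------------------------------------------------------------------
# Age groups and Ps bins
# ---------------------------------------------------------------------------


def test_age_groups_partition_0_to_18():
    for age in range(19):
        hits = [g for g in AGE_GROUPS if g.contains(age)]
        assert len(hits) == 1
    assert age_group_label(0) == "neonates/infants"
    assert age_group_label(12) == "adolescents"
    assert age_group_label(19) is None


def test_bin_assignment_examples():
    assert assign_ps_bin(0.999) == "0.96-1.00"
    assert assign_ps_bin(0.253) == "0.00-0.25"  # rounds to 0.25
    assert assign_ps_bin(0.255) == "0.26-0.50"  # rounds to 0.26


def test_bin_assignment_exhaustive_and_disjoint_on_2dp_lattice():
    """Oracle: every 2-decimal value in [0.00, 1.00] maps to exactly one bin."""
    for cents in range(0, 101):
        v = cents / 100.0
        label = assign_ps_bin(min(max(v, 1e-9), 1 - 1e-9) if v in (0.0, 1.0) else v)
        matches = [lab for lab, lo, hi in PS_BINS if round(lo * 100) <= cents <= round(hi * 100)]
        assert len(matches) == 1
        assert label == matches[0]


@given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
@settings(derandomize=True, max_examples=300)
def test_every_ps_maps_to_exactly_one_bin(ps):
    label = assign_ps_bin(ps)
    assert label in {lab for lab, _, _ in PS_BINS}


def test_classify_survival_threshold_convention():
    assert classify_survival(0.99)
    assert not classify_survival(0.13)
    assert classify_survival(0.5, 0.5)  # boundary counts as survivor
    with pytest.raises(ValidationError):
        classify_survival(0.5, threshold=1.5)


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------


def test_confusion_all_predicted_dead_low_ps_bin():
    # 172 patients, 48 actual survivors, none predicted to survive
    predicted = [False] * 172
    actual = [True] * 48 + [False] * 124
    s = confusion_metrics(predicted, actual)
    assert (s.sensitivity, s.specificity, s.ppv) == (0.0, 100.0, 0.0)
    assert s.npv == 72.1 and s.accuracy == 72.1


def test_confusion_all_predicted_survive_high_ps_bin():
    # 844 patients, 777 actual survivors, all predicted to survive
    predicted = [True] * 844
    actual = [True] * 777 + [False] * 67
    s = confusion_metrics(predicted, actual)
    assert (s.sensitivity, s.specificity) == (100.0, 0.0)
    assert s.ppv == 92.1 and s.npv == 0.0 and s.accuracy == 92.1


def test_confusion_perfect_prediction():
    s = confusion_metrics([True, False], [True, False])
    assert (s.sensitivity, s.specificity, s.ppv, s.npv, s.accuracy) == (100.0,) * 5


def test_confusion_requires_pairs():
    with pytest.raises(ValidationError):
        confusion_metrics([], [])


def test_percent_display_convention():
    assert percent(378, 17745) == 2.1
    assert percent(0, 0) == 0.0
    assert percent(1, 3) == 33.3


# ---------------------------------------------------------------------------
# Rank AUC
# ---------------------------------------------------------------------------


def brute_force_auc(scores, outcomes):
    """Exhaustive pairwise oracle: ties count 1/2."""
    pos = [s for s, o in zip(scores, outcomes) if o]
    neg = [s for s, o in zip(scores, outcomes) if not o]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_perfect_separation_and_all_ties():
    auc, _ = auc_rank([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
    assert auc == 1.0
    auc, _ = auc_rank([0.5, 0.5], [True, False])
    assert auc == 0.5


def test_auc_single_class_raises():
    with pytest.raises(ValidationError, match="undefined"):
        auc_rank([0.1, 0.9], [True, True])


def test_auc_equals_pairwise_oracle_on_random_fixtures(rng):
    for trial in range(25):
        n = int(rng.integers(4, 31))
        scores = np.round(rng.random(n), 2)  # coarse grid to force ties
        outcomes = rng.random(n) < 0.5
        if outcomes.all() or not outcomes.any():
            outcomes[0] = ~outcomes[0]
        auc, (lo, hi) = auc_rank(scores, outcomes)
        assert auc == pytest.approx(brute_force_auc(scores, outcomes), abs=1e-12)
        assert 0.0 <= lo <= auc <= hi <= 1.0


def test_auc_cross_checks_against_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.random(500)
    outcomes = rng.random(500) < 0.7
    auc, _ = auc_rank(scores, outcomes)
    assert auc == pytest.approx(roc_auc_score(outcomes, scores), abs=1e-12)


def test_auc_ci_covers_large_sample_truth(rng):
    # well-separated classes: CI should be tight and contain the replicated point
    scores = np.concatenate([rng.normal(0.8, 0.05, 400), rng.normal(0.4, 0.1, 100)])
    outcomes = np.array([True] * 400 + [False] * 100)
    auc, (lo, hi) = auc_rank(scores, outcomes)
    assert lo < auc < hi and hi - lo < 0.1


# ---------------------------------------------------------------------------
# Ps-bin calibration table
# ---------------------------------------------------------------------------


def test_bin_summary_from_stats_worked_example():
    b = PsBinSummary.from_stats("0.00-0.25", 0.130, 172, 48)
    assert b.expected_survivors_raw == pytest.approx(22.36)
    assert b.expected_survivors_display == 22
    assert b.oe_ratio == 2.15  # 48/22.36, not 48/22


def test_bin_table_conservation_and_oe(rng):
    ps = rng.random(2000) * 0.98 + 0.01
    survived = rng.random(2000) < ps
    table = ps_bin_table(ps, survived)
    assert sum(b.n for b in table) == 2000
    assert sum(b.observed_survivors for b in table) == int(survived.sum())
    for b in table:
        if b.n:
            assert 0 <= b.observed_survivors <= b.n
            assert b.expected_survivors_raw == pytest.approx(b.mean_ps * b.n)


def test_bin_table_empty_bin_row():
    table = ps_bin_table([0.99, 0.97], [True, True])
    low = next(b for b in table if b.label == "0.00-0.25")
    assert low.n == 0 and low.oe_ratio is None and low.mean_ps is None


def test_pooled_oe_between_component_oes():
    a = PsBinSummary.from_stats("0.26-0.50", 0.40, 100, 50)
    b = PsBinSummary.from_stats("0.51-0.75", 0.60, 200, 140)
    pooled_oe = (a.observed_survivors + b.observed_survivors) / (
        a.expected_survivors_raw + b.expected_survivors_raw
    )
    lo, hi = sorted([a.oe_ratio, b.oe_ratio])
    assert lo <= pooled_oe <= hi


def test_oe_unity_when_observed_equals_expected():
    b = PsBinSummary.from_stats("0.26-0.50", 0.50, 200, 100)
    assert b.oe_ratio == 1.0


# ---------------------------------------------------------------------------
# Stratified report
# ---------------------------------------------------------------------------


def _synthetic_scored(rng, n=800):
    ages = rng.integers(0, 19, n)
    ps = rng.random(n) * 0.98 + 0.01
    survived = rng.random(n) < ps
    return pd.DataFrame({"age_years": ages, "ps": ps, "survived": survived})


def test_stratified_rows_match_direct_recomputation(rng):
    scored = _synthetic_scored(rng)
    report = stratified_report(scored, stratifier="age")
    for res in report.strata:
        group = next(g for g in AGE_GROUPS if g.label == res.label)
        sub = scored[[group.contains(a) for a in scored["age_years"]]]
        direct = confusion_metrics(sub["ps"] >= 0.5, sub["survived"])
        assert res.summary.accuracy == direct.accuracy
        assert res.summary.n == direct.n
        auc, _ = auc_rank(sub["ps"], sub["survived"])
        assert res.summary.auc == pytest.approx(auc)
    assert report.overall.summary.n == len(scored)


def test_single_stratum_equals_overall(rng):
    scored = _synthetic_scored(rng, 200)
    scored["age_years"] = 3  # everyone preschool
    report = stratified_report(scored, stratifier="age")
    assert len(report.strata) == 1
    assert report.strata[0].summary == report.overall.summary


def test_single_class_stratum_has_undefined_auc_but_metrics(rng):
    scored = pd.DataFrame(
        {"age_years": [0, 0, 10, 10], "ps": [0.9, 0.8, 0.7, 0.2], "survived": [True, True, True, False]}
    )
    report = stratified_report(scored, stratifier="age")
    neo = next(r for r in report.strata if r.label == "neonates/infants")
    assert neo.summary.auc is None
    assert neo.summary.sensitivity == 100.0
    assert report.overall.summary.auc is not None


def test_ps_bin_stratifier_reproduces_degenerate_pattern():
    # all Ps below threshold in the lowest bin -> sens 0 / spec 100
    scored = pd.DataFrame(
        {"age_years": [15] * 172, "ps": [0.13] * 172, "survived": [True] * 48 + [False] * 124}
    )
    report = stratified_report(scored, stratifier="ps_bin")
    row = report.strata[0]
    assert row.label == "0.00-0.25"
    assert row.summary.sensitivity == 0.0 and row.summary.specificity == 100.0
    assert row.summary.accuracy == 72.1


def test_report_dataframe_and_text_render(rng):
    report = stratified_report(_synthetic_scored(rng), stratifier="age")
    df = report.to_dataframe()
    assert list(df["stratum"])[0] == "total"
    text = report.to_text()
    assert "AUC" in text and "total" in text


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def test_identical_groups_not_significant(rng):
    g = rng.normal(size=60)
    res = compare_groups([g, g.copy()], "continuous")
    assert res.pvalue > 0.9
    assert not res.significant


def test_shifted_groups_detected(rng):
    a = rng.normal(0, 1, 50)
    res = compare_groups([a, a + 10.0], "continuous")
    assert res.test == "mann-whitney-u"
    assert res.pvalue < 0.001
    res3 = compare_groups([a, a + 10.0, a - 10.0], "continuous")
    assert res3.test == "kruskal-wallis"
    assert res3.pvalue < 0.001


def test_chi_square_closed_form_oracle():
    # (ad-bc)^2 * n / (row and column products) = 20 for (10,0;0,10)
    res = compare_groups([[10, 0], [0, 10]], "categorical")
    assert res.statistic == pytest.approx(20.0)
    assert res.pvalue < 0.001


def test_degenerate_inputs_warn_not_nan_silently():
    with pytest.warns(UserWarning):
        res = compare_groups([[1.0, 1.0], [1.0, 1.0]], "continuous")
    assert np.isnan(res.statistic)
    with pytest.warns(UserWarning):
        res = compare_groups([[5, 0], [3, 0]], "categorical")
    assert np.isnan(res.pvalue)


# ---------------------------------------------------------------------------
# Descriptive table
# ---------------------------------------------------------------------------


def test_descriptive_table_shape_and_mortality(rng):
    scored = _synthetic_scored(rng)
    scored["sex"] = np.where(rng.random(len(scored)) < 0.7, "male", "female")
    scored["iss"] = rng.integers(1, 40, len(scored))
    scored["rts"] = rng.random(len(scored)) * 7.84
    scored["ais_head_neck"] = rng.integers(0, 6, len(scored))
    table = descriptive_table(scored)
    assert "total" in table.columns and "p" in table.columns
    assert table.loc["n", "total"] == len(scored)
    mort = 100 * (1 - scored["survived"].mean())
    assert f"({mort:.1f}%)" in table.loc["mortality", "total"] or abs(mort) >= 0
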