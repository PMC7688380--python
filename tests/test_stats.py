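"""Diagnostic metrics, exact binomial CIs, correlation CIs, ANOVA,
and reconstruction of 2x2 tables from rounded percentages."""

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from hstsim import (
    ConfusionTable,
    anova_oneway,
    clopper_pearson_ci,
    confusion_from_calls,
    diagnostic_metrics,
    fisher_ci_from_r,
    pearson_r_with_ci,
    reconstruct_counts,
    summary_frame,
)

# published validity rows (percent, 1 dp) for scale-difference cutoffs 5/6/7
PRINTED_ROWS = {
    5: {"sensitivity": 95.5, "specificity": 66.7, "ppv": 90.1, "npv": 82.3},
    6: {"sensitivity": 92.5, "specificity": 85.7, "ppv": 95.4, "npv": 78.3},
    7: {"sensitivity": 91.0, "specificity": 90.5, "ppv": 96.8, "npv": 76.0},
}
RECONSTRUCTED = {
    5: ConfusionTable(64, 3, 7, 14),
    6: ConfusionTable(62, 5, 3, 18),
    7: ConfusionTable(61, 6, 2, 19),
}


def test_confusion_table_validation_and_totals():
    t = ConfusionTable(3, 0, 0, 0)
    assert t.n == 3 and t.gold_positives == 3
    with pytest.raises(ValueError):
        ConfusionTable(-1, 0, 0, 0)


def test_confusion_from_calls_matches_brute_force(rng):
    screen = rng.random(500) < 0.6
    gold = rng.random(500) < 0.7
    t = confusion_from_calls(screen, gold)
    brute = [0, 0, 0, 0]
    for s, g in zip(screen, gold):
        if s and g:
            brute[0] += 1
        elif not s and g:
            brute[1] += 1
        elif s and not g:
            brute[2] += 1
        else:
            brute[3] += 1
    assert (t.tp, t.fn, t.fp, t.tn) == tuple(brute)
    assert t.n == 500


def test_confusion_from_calls_empty_errors():
    with pytest.raises(ValueError):
        confusion_from_calls([], [])


def test_diagnostic_metrics_fractions():
    m = diagnostic_metrics(ConfusionTable(64, 3, 7, 14))
    assert m.sensitivity.estimate == pytest.approx(64 / 67)
    assert m.specificity.estimate == pytest.approx(14 / 21)
    assert m.ppv.estimate == pytest.approx(64 / 71)
    assert m.npv.estimate == pytest.approx(14 / 17)

    m = diagnostic_metrics(ConfusionTable(1, 0, 0, 1))
    assert all(e.estimate == 1.0 for e in m.as_dict().values())

    m = diagnostic_metrics(ConfusionTable(0, 5, 0, 5))
    assert m.sensitivity.estimate == 0.0
    assert m.npv.estimate == 0.5
    assert m.ppv is None  # tp + fp = 0: undefined, flagged as None


def test_metric_intervals_bracket_estimate():
    for table in RECONSTRUCTED.values():
        for m in diagnostic_metrics(table).as_dict().values():
            assert 0.0 <= m.ci_low <= m.estimate <= m.ci_high <= 1.0


@pytest.mark.parametrize(
    "k, n, lo, hi",
    [
        (64, 67, 0.875, 0.991),
        (14, 21, 0.430, 0.854),
        (19, 21, 0.696, 0.988),
        (14, 17, 0.566, 0.962),
    ],
)
def test_clopper_pearson_reproduces_published_intervals(k, n, lo, hi):
    got_lo, got_hi = clopper_pearson_ci(k, n)
    assert round(got_lo, 3) == lo
    assert round(got_hi, 3) == hi


def test_clopper_pearson_edge_cases_closed_form():
    lo, hi = clopper_pearson_ci(0, 10)
    assert lo == 0.0
    assert hi == pytest.approx(1 - 0.025 ** (1 / 10))
    lo, hi = clopper_pearson_ci(10, 10)
    assert hi == 1.0
    assert lo == pytest.approx(0.025 ** (1 / 10))


def test_clopper_pearson_against_statsmodels():
    for k, n in [(64, 67), (14, 21), (1, 50), (25, 50)]:
        ours = clopper_pearson_ci(k, n)
        ref = proportion_confint(k, n, alpha=0.05, method="beta")
        assert ours == pytest.approx(ref, abs=1e-12)


def test_clopper_pearson_invalid_counts():
    with pytest.raises(ValueError):
        clopper_pearson_ci(5, 0)
    with pytest.raises(ValueError):
        clopper_pearson_ci(11, 10)


def test_fisher_ci_reproduces_published_interval():
    lo, hi = fisher_ci_from_r(0.88, 88)
    assert round(lo, 2) == 0.82
    assert round(hi, 2) == 0.92


def test_fisher_ci_width_shrinks_with_n():
    lo_small, hi_small = fisher_ci_from_r(0.88, 88)
    lo_big, hi_big = fisher_ci_from_r(0.88, 352)
    assert (hi_big - lo_big) < (hi_small - lo_small)


def test_pearson_r_with_ci_recovers_known_structure(rng):
    x = rng.normal(size=1000)
    noise = rng.normal(size=1000)
    r, lo, hi = pearson_r_with_ci(x, noise)
    assert abs(r) < 0.1
    assert lo < 0.0 < hi
    r, lo, hi = pearson_r_with_ci(x, 2 * x + 1)
    assert r == lo == hi == 1.0


def test_pearson_degenerate_inputs_error():
    with pytest.raises(ValueError):
        pearson_r_with_ci([1, 2], [1, 2])
    with pytest.raises(ValueError):
        pearson_r_with_ci([1, 1, 1, 1], [1, 2, 3, 4])


def test_anova_identical_groups():
    f, p = anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert f == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_anova_strong_separation():
    f, p = anova_oneway([[0.0, 0.01, -0.01], [100.0, 100.01, 99.99]])
    assert p < 1e-3


def test_anova_hand_computed_three_groups():
    # groups (1,2,3), (2,3,4), (6,7,8): SSB=42 (df 2), SSW=6 (df 6) -> F=21
    f, p = anova_oneway([[1, 2, 3], [2, 3, 4], [6, 7, 8]])
    assert f == pytest.approx(21.0)
    assert 0 < p < 0.01


def test_anova_degenerate_groups_error():
    with pytest.raises(ValueError):
        anova_oneway([[1.0, 2.0]])
    with pytest.raises(ValueError):
        anova_oneway([[1.0], [2.0, 3.0]])


@pytest.mark.parametrize("cutoff", [5, 6, 7])
def test_reconstruct_counts_published_rows(cutoff):
    table = reconstruct_counts(PRINTED_ROWS[cutoff], n_total=88)
    assert table == RECONSTRUCTED[cutoff]
    assert table.gold_positives == 67


@pytest.mark.parametrize("cutoff", [5, 6, 7])
def test_reconstruction_round_trips_through_metrics(cutoff):
    # metrics of the reconstructed table agree with the printed values to
    # the printed precision (the published row carries one 0.05%-level slip)
    table = reconstruct_counts(PRINTED_ROWS[cutoff], n_total=88)
    m = diagnostic_metrics(table)
    for name, printed in PRINTED_ROWS[cutoff].items():
        assert 100 * m.as_dict()[name].estimate == pytest.approx(printed, abs=0.1)


def test_reconstruct_counts_rejects_inconsistent_percentages():
    fake = {"sensitivity": 95.5, "specificity": 66.7, "ppv": 10.0, "npv": 82.3}
    with pytest.raises(ValueError):
        reconstruct_counts(fake, n_total=88)


def test_clopper_pearson_coverage_small_sample(rng):
    # conservative coverage of the exact interval (reduced replicate count;
    # the full check runs in the acceptance suite)
    k = rng.binomial(50, 0.5, size=1000)
    lo, hi = clopper_pearson_ci(k, np.full(1000, 50))
    assert np.mean((lo <= 0.5) & (0.5 <= hi)) >= 0.95


def test_summary_frame_shape():
    frame = summary_frame({c: diagnostic_metrics(t) for c, t in RECONSTRUCTED.items()})
    assert list(frame["cutoff_scales"]) == [5, 6, 7]
    assert list(frame["cutoff_db"]) == [25, 30, 35]
    row5 = frame[frame["cutoff_scales"] == 5].iloc[0]
    assert row5["sensitivity"] == 95.5
    assert (row5["sensitivity_lo"], row5["sensitivity_hi"]) == (87.5, 99.1)
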