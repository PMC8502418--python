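"""Exact binomial CIs, diagnostic metrics, rank AUC and dilution linearity."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from dropmeth.calling import call_cohort, default_panel
from dropmeth.performance import (
    clopper_pearson,
    diagnostic_performance,
    linearity,
    roc_auc,
)
from dropmeth.records import DegenerateDataError, ValidationError
from dropmeth.simulate import (
    DILUTION_CONCENTRATIONS_NG_PER_UL,
    SimConfig,
    simulate_dilution_series,
)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n", [(0, 7), (1, 12), (5, 10), (21, 22), (10, 10), (99, 100)])
    def test_matches_independent_beta_oracle(self, k, n):
        lo, hi = clopper_pearson(k, n, 0.95)
        olo, ohi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(0.0 if k == 0 else olo, abs=1e-12)
        assert hi == pytest.approx(1.0 if k == n else ohi, abs=1e-12)

    def test_boundary_cases(self):
        assert clopper_pearson(0, 7)[0] == 0.0
        assert clopper_pearson(7, 7)[1] == 1.0

    def test_all_successes_lower_bound_closed_form(self):
        # for k = n the lower bound solves p^n = alpha/2
        lo, _ = clopper_pearson(10, 10, 0.95)
        assert lo == pytest.approx(0.025 ** (1 / 10), rel=1e-12)

    def test_interval_narrows_with_sample_size(self):
        w1 = np.diff(clopper_pearson(5, 10))[0]
        w2 = np.diff(clopper_pearson(50, 100))[0]
        w3 = np.diff(clopper_pearson(500, 1000))[0]
        assert w1 > w2 > w3

    @pytest.mark.parametrize("k,n,conf", [(-1, 10, 0.95), (11, 10, 0.95), (1, 0, 0.95), (1, 10, 1.5)])
    def test_invalid_inputs_rejected(self, k, n, conf):
        with pytest.raises(ValidationError):
            clopper_pearson(k, n, conf)


class TestDiagnosticPerformance:
    def test_published_cohort_metrics(self, published_plasma_cohort, panel):
        counts, _, truth = published_plasma_cohort
        calls = call_cohort(counts, panel, rule="any")
        summary = diagnostic_performance(calls, truth)
        assert summary.tp == 21 and summary.fn == 1
        assert summary.tn == 10 and summary.fp == 0
        r = summary.rounded()
        assert r["sensitivity_pct"] == 95.5
        assert r["sensitivity_ci_pct"] == [77, 100]
        assert r["specificity_pct"] == 100.0
        assert r["specificity_ci_pct"] == [69, 100]

    def test_perfect_classifier(self, published_plasma_cohort, panel):
        counts, _, truth = published_plasma_cohort
        calls = call_cohort(counts, panel, rule="any")
        forced = {c.sample_id: truth[c.sample_id] for c in calls}
        perfect = [type(c)(c.sample_id, c.marker_calls, forced[c.sample_id], c.rule) for c in calls]
        summary = diagnostic_performance(perfect, truth)
        assert summary.sensitivity == 1.0 and summary.specificity == 1.0

    def test_confusion_counts_partition_classes(self, published_plasma_cohort, panel):
        counts, _, truth = published_plasma_cohort
        summary = diagnostic_performance(call_cohort(counts, panel), truth)
        assert summary.tp + summary.fn == summary.n_cases == 22
        assert summary.tn + summary.fp == summary.n_controls == 10

    def test_random_calls_match_binomial_oracle(self, published_plasma_cohort, panel):
        # coin-flip calls on a large balanced cohort: both metrics converge
        # to the positive-call rate
        rng = np.random.default_rng(8)
        n, p = 2_000, 0.3
        from dropmeth.calling import CallResult

        calls, truth = [], {}
        for i in range(n):
            sid = f"s{i}"
            calls.append(CallResult(sid, (), bool(rng.random() < p), "any"))
            truth[sid] = i < n // 2
        summary = diagnostic_performance(calls, truth)
        se = math.sqrt(p * (1 - p) / (n // 2))
        assert abs(summary.sensitivity - p) < 3 * se
        assert abs((1 - summary.specificity) - p) < 3 * se

    def test_missing_truth_label_rejected(self, published_plasma_cohort, panel):
        counts, _, truth = published_plasma_cohort
        calls = call_cohort(counts, panel)
        truth = dict(truth)
        truth.pop(calls[0].sample_id)
        with pytest.raises(ValidationError, match="without truth"):
            diagnostic_performance(calls, truth)

    def test_single_class_metric_reported_absent(self, published_plasma_cohort, panel):
        counts, _, truth = published_plasma_cohort
        calls = [c for c in call_cohort(counts, panel) if truth[c.sample_id]]
        summary = diagnostic_performance(calls, truth)
        assert summary.specificity is None and summary.spec_ci is None
        assert summary.sensitivity is not None


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=0)
        assert res.auc == 1.0

    def test_pair_enumeration_example(self):
        # cases score {2, 4}, controls {1, 3}: 3 of 4 pairs won
        res = roc_auc([1, 2, 3, 4], [False, True, False, True], n_boot=0)
        assert res.auc == 0.75

    def test_all_tied_scores_give_half(self):
        res = roc_auc([5, 5, 5, 5], [0, 0, 1, 1], n_boot=0)
        assert res.auc == 0.5

    def test_label_flip_complements(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = rng.random(40) < 0.5
        y[0], y[1] = True, False  # both classes present
        a = roc_auc(s, y, n_boot=0).auc
        b = roc_auc(s, ~y, n_boot=0).auc
        assert a == pytest.approx(1 - b)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=30)
        y = np.zeros(30, bool)
        y[:12] = True
        a = roc_auc(s, y, n_boot=0).auc
        b = roc_auc(np.exp(2.0 * s) + 7.0, y, n_boot=0).auc
        assert a == pytest.approx(b)

    def test_bootstrap_interval_brackets_point(self):
        rng = np.random.default_rng(2)
        s = np.concatenate([rng.normal(0, 1, 30), rng.normal(1.5, 1, 30)])
        y = np.concatenate([np.zeros(30, bool), np.ones(30, bool)])
        res = roc_auc(s, y, n_boot=500, seed=0)
        assert res.ci[0] <= res.auc <= res.ci[1]

    def test_deterministic_under_seed(self):
        s = [1, 3, 2, 5, 4, 8]
        y = [0, 0, 0, 1, 1, 1]
        assert roc_auc(s, y, n_boot=200, seed=3) == roc_auc(s, y, n_boot=200, seed=3)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [1, 1, 1], n_boot=0)


class TestLinearity:
    def test_exact_line(self):
        res = linearity([0.5, 0.25, 0.1, 0.05, 0.01], [50, 25, 10, 5, 1])
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(100.0)

    def test_order_invariance(self):
        x = [0.5, 0.25, 0.1, 0.05, 0.01]
        y = [48.0, 26.0, 11.0, 4.0, 1.5]
        a = linearity(x, y)
        b = linearity(x[::-1], y[::-1])
        assert a.slope == pytest.approx(b.slope)
        assert a.r_squared == pytest.approx(b.r_squared)

    def test_simulated_dilution_series_is_linear(self):
        # the 10%-methylated dilution design at the five standard inputs:
        # with Poisson counting noise and blank false positives included,
        # the per-marker fit stays strongly linear across seeds
        r2 = {"NPY": [], "WIF1": []}
        for seed in range(20):
            wells = simulate_dilution_series(SimConfig(seed=seed))
            for marker in r2:
                means = [
                    np.mean([
                        w.n_positive
                        for w in wells
                        if w.marker == marker and w.well_id.startswith(f"dil_{marker}_{c}_")
                    ])
                    for c in DILUTION_CONCENTRATIONS_NG_PER_UL
                ]
                r2[marker].append(linearity(DILUTION_CONCENTRATIONS_NG_PER_UL, means).r_squared)
        assert np.median(r2["NPY"]) >= 0.95
        assert np.median(r2["WIF1"]) >= 0.95

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDataError):
            linearity([0.1, 0.1, 0.1], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            linearity([0.1, 0.2], [1, 2])
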