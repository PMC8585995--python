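"""Diagnostic-accuracy statistics against independent oracles and the
published validation cohort's printed counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddscreen import (
    ConfusionMatrix,
    accuracy_metrics,
    build_confusion_matrix,
    concordance_frame,
    concordance_table,
    flags_to_frame,
    pearson_chi_square,
    two_sample_t,
)
from ddscreen.model import Disorder, DisorderFlag, FlagSource

# Published 2x2 cells of the n=213 validation cohort (TN, FN, TP, FP).
TABLE2_CELLS = {
    Disorder.depression: (121, 17, 63, 12),
    Disorder.gad: (159, 28, 23, 3),
    Disorder.ptsd: (124, 41, 39, 9),
    Disorder.social_phobia: (168, 28, 15, 2),
    Disorder.adhd: (149, 19, 39, 6),
    Disorder.dysthymia: (181, 16, 14, 2),
    Disorder.psychosis: (151, 25, 30, 7),
    Disorder.mania: (189, 13, 8, 1),
}


def cm_from_cells(tn, fn, tp, fp):
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


class TestBuildConfusionMatrix:
    def test_simple_pairs(self):
        cm = build_confusion_matrix([True, False], [True, False])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_exhaustive_2x2_of_outcomes(self):
        cm = build_confusion_matrix([True, True, False, False], [True, False, True, False])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_loop_and_count_oracle(self, pairs):
        index = [p[0] for p in pairs]
        reference = [p[1] for p in pairs]
        tp = fp = fn = tn = 0
        for i, r in pairs:  # independent per-pair tally
            if i and r:
                tp += 1
            elif i and not r:
                fp += 1
            elif not i and r:
                fn += 1
            else:
                tn += 1
        cm = build_confusion_matrix(index, reference)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            build_confusion_matrix([True], [True, False])
        with pytest.raises(ValueError):
            build_confusion_matrix([], [])


class TestAccuracyMetrics:
    def test_depression_screen_prevalence_from_published_cells(self):
        rep = accuracy_metrics(cm_from_cells(*TABLE2_CELLS[Disorder.depression]))
        assert rep.screen_prevalence_pct == pytest.approx(35.2, abs=0.05)

    def test_depression_sensitivity_from_counts(self):
        # 63/80: the direct quotient of the printed cells
        rep = accuracy_metrics(cm_from_cells(*TABLE2_CELLS[Disorder.depression]))
        assert rep.sensitivity.value == pytest.approx(63 / 80)
        assert rep.specificity.value == pytest.approx(121 / 133)

    def test_perfect_test(self):
        rep = accuracy_metrics(ConfusionMatrix(tp=10, fp=0, fn=0, tn=10))
        for m in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert m.value == 1.0

    def test_zero_denominator_flags_metric_and_computes_the_rest(self):
        rep = accuracy_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=5))
        assert not rep.sensitivity.defined and not rep.ppv.defined
        assert rep.specificity.value == 1.0 and rep.npv.value == 1.0

    @given(
        st.integers(1, 200), st.integers(1, 200), st.integers(1, 200), st.integers(1, 200)
    )
    @settings(max_examples=200, deadline=None)
    def test_bayes_consistency_of_ppv(self, tp, fp, fn, tn):
        """PPV equals se*pi / (se*pi + (1-sp)(1-pi)) with pi the reference
        prevalence, for all-positive-cell matrices."""
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        rep = accuracy_metrics(cm)
        pi = (tp + fn) / cm.n
        se, sp = rep.sensitivity.value, rep.specificity.value
        expected = se * pi / (se * pi + (1 - sp) * (1 - pi))
        assert rep.ppv.value == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_wilson_in_unit_interval_wald_clipped_and_flagged(self, tp, fn):
        if tp + fn == 0:
            tp = 1
        cm = ConfusionMatrix(tp=tp, fp=1, fn=fn, tn=1)
        wilson = accuracy_metrics(cm, ci="wilson").sensitivity
        assert 0.0 <= wilson.ci_low <= wilson.ci_high <= 1.0
        wald = accuracy_metrics(cm, ci="wald").sensitivity
        assert 0.0 <= wald.ci_low <= wald.ci_high <= 1.0  # post-clip
        raw_half = 1.959963984540054 * np.sqrt(
            wald.value * (1 - wald.value) / (tp + fn)
        )
        out_of_range = wald.value - raw_half < 0 or wald.value + raw_half > 1
        assert wald.ci_clipped == out_of_range


class TestChiSquare:
    @pytest.mark.parametrize(
        "cells, expected_stat, expected_df",
        [
            ([[139, 63], [10, 1]], 2.42, 1),  # sex x group
            ([[0, 3], [15, 7], [119, 46], [15, 8]], 7.63, 3),  # education x group
            ([[65, 35], [5, 3], [58, 19], [19, 5], [2, 2]], 4.16, 4),  # income
        ],
    )
    def test_reproduces_published_group_comparisons(self, cells, expected_stat, expected_df):
        res = pearson_chi_square(cells)
        assert res.statistic == pytest.approx(expected_stat, abs=0.005)
        assert res.df == expected_df

    def test_proportional_rows_give_zero(self):
        res = pearson_chi_square([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_chi_square_equals_cellwise_oracle_on_random_tables(self):
        """Statistic matches an independent expected-matrix construction on
        1,000 random small tables."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            r, c = rng.integers(2, 5, size=2)
            counts = rng.integers(1, 30, size=(r, c))
            res = pearson_chi_square(counts)
            # oracle: build expected counts cell by cell
            total = counts.sum()
            stat = 0.0
            for i in range(r):
                for j in range(c):
                    e = counts[i].sum() * counts[:, j].sum() / total
                    stat += (counts[i, j] - e) ** 2 / e
            assert res.statistic == pytest.approx(stat, rel=1e-10)
            assert res.df == (r - 1) * (c - 1)
            assert res.expected.sum(axis=1) == pytest.approx(counts.sum(axis=1))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_square([[0, 0], [1, 2]])

    def test_yates_correction_reduces_2x2_statistic(self):
        plain = pearson_chi_square([[139, 63], [10, 1]]).statistic
        corrected = pearson_chi_square([[139, 63], [10, 1]], yates=True).statistic
        assert corrected < plain


class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        res = two_sample_t(5.0, 1.0, 30, 5.0, 1.0, 30)
        assert res.statistic == pytest.approx(0.0)

    def test_pooled_t_for_published_age_summaries(self):
        # closed-form pooled-t oracle on the printed group summaries
        res = two_sample_t(30.20, 10.99, 149, 33.15, 11.21, 64, variant="pooled")
        sp2 = (148 * 10.99**2 + 63 * 11.21**2) / 211
        t_oracle = (30.20 - 33.15) / np.sqrt(sp2 * (1 / 149 + 1 / 64))
        assert res.statistic == pytest.approx(t_oracle)
        assert abs(res.statistic) == pytest.approx(1.79, abs=0.01)
        assert res.df == 211

    def test_doubling_group_sizes_scales_t_by_sqrt2(self):
        base = two_sample_t(10, 2, 40, 11, 2.5, 50).statistic
        doubled = two_sample_t(10, 2, 80, 11, 2.5, 100).statistic
        assert doubled / base == pytest.approx(np.sqrt(2), rel=1e-3)

    def test_welch_df_below_pooled_when_variances_differ(self):
        pooled = two_sample_t(10, 1, 20, 12, 5, 60, variant="pooled")
        welch = two_sample_t(10, 1, 20, 12, 5, 60, variant="welch")
        assert welch.df < pooled.df

    def test_degenerate_zero_variance_is_flagged(self):
        res = two_sample_t(5, 0, 10, 5, 0, 10)
        assert not res.defined and res.statistic is None


def _paired_cohort(n, rng, p_missing=0.0):
    disorders = [Disorder.depression, Disorder.mania]
    index = {}
    reference = {}
    for i in range(n):
        rid = f"R{i:03d}"
        index[rid] = []
        reference[rid] = []
        for d in disorders:
            if rng.random() >= p_missing:
                reference[rid].append(
                    DisorderFlag(disorder=d, probable=bool(rng.random() < 0.3),
                                 source=FlagSource.reference_mini)
                )
            if rng.random() >= p_missing:
                index[rid].append(
                    DisorderFlag(disorder=d, probable=bool(rng.random() < 0.3))
                )
    return flags_to_frame(index, reference)


class TestConcordanceTable:
    def test_identical_flags_give_perfect_rows(self):
        rng = np.random.default_rng(3)
        flags = {
            f"R{i}": [DisorderFlag(disorder=Disorder.gad, probable=bool(rng.random() < 0.4))]
            for i in range(40)
        }
        frame = flags_to_frame(flags, flags)
        rows = concordance_table(frame)
        assert rows[0].report.sensitivity.value == 1.0
        assert rows[0].report.specificity.value == 1.0

    def test_random_cohort_matches_compositional_oracle(self):
        rng = np.random.default_rng(11)
        frame = _paired_cohort(120, rng)
        rows = concordance_table(frame)
        assert [r.disorder for r in rows] == [Disorder.depression, Disorder.mania]
        for row in rows:
            icol = f"{row.disorder.value}_index"
            rcol = f"{row.disorder.value}_reference"
            cm = build_confusion_matrix(
                frame[icol].astype(bool).tolist(), frame[rcol].astype(bool).tolist()
            )
            assert (row.cm.tp, row.cm.fp, row.cm.fn, row.cm.tn) == (cm.tp, cm.fp, cm.fn, cm.tn)
            rep = accuracy_metrics(cm)
            assert row.report.sensitivity.value == rep.sensitivity.value

    def test_complete_case_count_conservation(self):
        rng = np.random.default_rng(5)
        frame = _paired_cohort(150, rng, p_missing=0.15)
        for row in concordance_table(frame):
            assert row.cm.n + row.dropped == len(frame)
            assert row.dropped > 0  # missingness was injected

    def test_missing_reference_column_is_configuration_error(self):
        frame = pd.DataFrame({"depression_index": [1.0, 0.0]})
        with pytest.raises(ValueError, match="reference"):
            concordance_table(frame)

    def test_frame_export_mirrors_published_layout(self):
        flags = {"R0": [DisorderFlag(disorder=Disorder.mania, probable=True)],
                 "R1": [DisorderFlag(disorder=Disorder.mania, probable=False)]}
        out = concordance_frame(concordance_table(flags_to_frame(flags, flags)))
        assert list(out.columns[:9]) == [
            "disorder", "sensitivity", "specificity", "ppv", "npv",
            "tn", "fn", "tp", "fp",
        ]
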