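"""Confusion metrics, aggregation arithmetic and report rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octliver import metrics as mx
from octliver.classifier import EpochTrace
from octliver.exceptions import CompletenessError, ParameterError
from octliver.volume_io import round_half_away


class TestConfusion:
    def test_enumerated_example(self):
        cm = mx.confusion(["tumor", "tumor", "healthy", "healthy"],
                          ["tumor", "healthy", "tumor", "healthy"])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_perfect_prediction_has_no_errors(self):
        labels = ["tumor", "healthy", "tumor"]
        cm = mx.confusion(labels, labels)
        assert cm.fp == cm.fn == 0

    def test_matches_bruteforce_pair_counting(self, rng):
        true = list(rng.choice(["healthy", "tumor"], 100))
        pred = list(rng.choice(["healthy", "tumor"], 100))
        cm = mx.confusion(true, pred)
        oracle = {
            (t, p): sum(1 for a, b in zip(true, pred) if (a, b) == (t, p))
            for t in ("tumor", "healthy") for p in ("tumor", "healthy")
        }
        assert cm.tp == oracle[("tumor", "tumor")]
        assert cm.fn == oracle[("tumor", "healthy")]
        assert cm.fp == oracle[("healthy", "tumor")]
        assert cm.tn == oracle[("healthy", "healthy")]
        assert cm.total == 100

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            mx.confusion(["tumor"], ["tumor", "healthy"])
        with pytest.raises(ParameterError):
            mx.confusion(["tumor"], ["benign"])


class TestMetricsFromCM:
    def test_hand_computed_example(self):
        row = mx.metrics_from_cm(mx.ConfusionMatrix(tp=9, fp=2, fn=1, tn=8))
        assert row.sensitivity == pytest.approx(0.90)
        assert row.specificity == pytest.approx(0.80)
        assert row.ppv == pytest.approx(9 / 11)
        assert row.npv == pytest.approx(8 / 9)
        assert row.accuracy == pytest.approx(0.85)
        assert row.f1 == pytest.approx(2 * (9 / 11) * 0.9 / ((9 / 11) + 0.9))

    def test_perfect_classifier_scores_one_everywhere(self):
        row = mx.metrics_from_cm(mx.ConfusionMatrix(tp=5, fp=0, fn=0, tn=7))
        assert all(getattr(row, m) == 1.0 for m in mx.METRIC_NAMES)

    def test_zero_denominators_reported_as_nan_with_reason(self):
        row = mx.metrics_from_cm(mx.ConfusionMatrix(tp=0, fp=0, fn=0, tn=4))
        assert math.isnan(row.sensitivity)
        assert "sensitivity" in row.undefined
        assert math.isnan(row.ppv)
        assert row.specificity == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            mx.metrics_from_cm(mx.ConfusionMatrix(0, 0, 0, 0))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 40), st.integers(0, 40), st.integers(0, 40), st.integers(1, 40))
    def test_metric_identities_on_random_matrices(self, tp, fp, fn, tn):
        cm = mx.ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        row = mx.metrics_from_cm(cm)
        pos, neg = tp + fn, tn + fp
        assert row.accuracy == pytest.approx(
            (row.sensitivity * pos + row.specificity * neg) / (pos + neg)
        )
        if not math.isnan(row.f1):
            assert row.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))


@pytest.fixture(scope="module")
def rows():
    return mx.load_reference_runs()


class TestReferenceTable:
    """The bundled 25-run benchmark metrics behave as published."""

    def test_f1_anchor_rows_recompute_from_ppv_and_sensitivity(self, rows):
        anchors = {"A1": 0.92, "B2": 0.96, "C1": 0.83}
        for run_id, expected in anchors.items():
            row = next(r for r in rows if r.run_id == run_id)
            assert round_half_away(mx.f1_from(row.ppv, row.sensitivity), 2) == expected

    def test_every_row_f1_consistent_within_rounding(self, rows):
        for row in rows:
            assert mx.f1_from(row.ppv, row.sensitivity) == pytest.approx(row.f1, abs=0.011)

    def test_aggregate_means_match_published_summary(self, rows):
        rep = mx.aggregate(rows)
        assert rep.n_runs == 25
        rounded = {m: round_half_away(rep.mean[m], 2) for m in mx.METRIC_NAMES}
        assert rounded == {
            "sensitivity": 0.94, "specificity": 0.93, "ppv": 0.92,
            "npv": 0.94, "accuracy": 0.93, "f1": 0.93,
        }
        assert round_half_away(rep.sd["f1"], 2) == 0.03
        assert round_half_away(rep.sd["sensitivity"], 2) == 0.04

    def test_published_metric_ranges(self, rows):
        rep = mx.aggregate(rows)
        assert (rep.min["sensitivity"], rep.max["sensitivity"]) == (0.86, 0.99)
        assert (rep.min["specificity"], rep.max["specificity"]) == (0.78, 0.96)
        assert rep.max["f1"] == 0.97


class TestAggregate:
    def test_identical_rows_have_zero_sd(self):
        row = mx.metrics_from_cm(mx.ConfusionMatrix(tp=9, fp=2, fn=1, tn=8))
        rep = mx.aggregate([row, row, row])
        assert all(rep.sd[m] == pytest.approx(0.0) for m in mx.METRIC_NAMES)
        assert all(rep.min[m] <= rep.mean[m] <= rep.max[m] for m in mx.METRIC_NAMES)

    def test_single_row_rejected(self):
        row = mx.metrics_from_cm(mx.ConfusionMatrix(tp=1, fp=0, fn=0, tn=1))
        with pytest.raises(ParameterError):
            mx.aggregate([row])

    def test_nan_rows_excluded_metric_wise(self):
        good = mx.metrics_from_cm(mx.ConfusionMatrix(tp=4, fp=1, fn=1, tn=4))
        nan_sens = mx.metrics_from_cm(mx.ConfusionMatrix(tp=0, fp=0, fn=0, tn=4))
        rep = mx.aggregate([good, good, nan_sens])
        assert rep.mean["sensitivity"] == pytest.approx(good.sensitivity)


class TestRendering:
    def test_table_layout_and_purity(self):
        rows = mx.load_reference_runs()
        rep = mx.aggregate(rows)
        text = mx.render_table(rows, rep, fmt="csv")
        lines = text.strip().splitlines()
        assert len(lines) == 1 + 25 + 2  # header + runs + Mean + SD
        assert lines[0].startswith("CNN,Sensitivity/Recall,Specificity,PPV/Precision,NPV,Accuracy,F1-score")
        assert lines[-2].startswith("Mean,")
        assert lines[-1].startswith("SD,")
        assert text == mx.render_table(rows, rep, fmt="csv")
        md = mx.render_table(rows, rep, fmt="markdown")
        assert md.count("\n") == 2 + 27

    def test_csv_round_trip_recovers_rendered_values(self):
        rows = mx.load_reference_runs()
        rep = mx.aggregate(rows)
        text = mx.render_table(rows, rep, fmt="csv")
        df = mx.parse_table_csv(text)
        a1 = df[df["CNN"] == "A1"].iloc[0]
        assert list(a1[1:]) == ["0.91", "0.95", "0.94", "0.92", "0.93", "0.92"]
        assert mx.render_table(rows, rep, fmt="csv") == text

    def test_missing_runs_raise_completeness_error(self):
        rows = [r for r in mx.load_reference_runs() if r.run_id != "C3"]
        rep = mx.aggregate(rows)
        with pytest.raises(CompletenessError, match="C3"):
            mx.render_table(rows, rep, fmt="csv")

    def test_learning_curves_written_as_csv_and_png(self, tmp_path):
        trace = EpochTrace(
            train_loss=[0.7, 0.5], val_loss=[0.8, 0.6],
            train_f1=[0.5, 0.8], val_f1=[0.4, 0.7],
        )
        files = mx.render_learning_curves({"A1": trace}, tmp_path)
        names = {f.name for f in files}
        assert names == {"learning_curve_A1.csv", "learning_curve_A1.png"}
        import pandas as pd

        df = pd.read_csv(tmp_path / "learning_curve_A1.csv")
        assert list(df["epoch"]) == [1, 2]
        assert list(df["val_f1"]) == [0.4, 0.7]
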