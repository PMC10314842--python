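"""Confusion-matrix metrics, cross-run aggregation and report rendering.

Conventions: the positive class is ``tumor``.  Sensitivity (recall) is
TP/(TP+FN), specificity TN/(TN+FP), PPV (precision) TP/(TP+FP), NPV
TN/(TN+FN), accuracy (TP+TN)/total and F1 the harmonic mean of PPV and
sensitivity.  A metric whose denominator is zero is reported as NaN with an
explicit reason rather than silently zero, so aggregates are never
corrupted.  Display rounding is half away from zero at two decimals; the
aggregate uses unrounded per-run values with the sample (n-1) standard
deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CompletenessError, ParameterError
from .volume_io import LABELS, round_half_away

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1")

_DISPLAY_COLUMNS = {
    "sensitivity": "Sensitivity/Recall",
    "specificity": "Specificity",
    "ppv": "PPV/Precision",
    "npv": "NPV",
    "accuracy": "Accuracy",
    "f1": "F1-score",
}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsRow:
    run_id: str
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    f1: float
    undefined: dict = field(default_factory=dict)  # metric -> reason

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class AggregateReport:
    n_runs: int
    mean: dict
    sd: dict
    min: dict
    max: dict


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count tumor-positive confusion cells from two label sequences."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ParameterError("label lists must have equal length")
    bad = {l for l in true_labels + predicted_labels if l not in LABELS}
    if bad:
        raise ParameterError(f"unknown labels: {sorted(bad)}")
    tp = fp = fn = tn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == "tumor":
            if p == "tumor":
                tp += 1
            else:
                fn += 1
        else:
            if p == "tumor":
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, name: str, undefined: dict) -> float:
    if den == 0:
        undefined[name] = f"denominator {den} (no items in that margin)"
        return math.nan
    return num / den


def metrics_from_cm(cm: ConfusionMatrix, run_id: str = "") -> MetricsRow:
    """Derive the six per-model metrics from a confusion matrix."""
    if cm.total == 0:
        raise ParameterError("empty confusion matrix")
    undefined: dict = {}
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity", undefined)
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity", undefined)
    ppv = _ratio(cm.tp, cm.tp + cm.fp, "ppv", undefined)
    npv = _ratio(cm.tn, cm.tn + cm.fn, "npv", undefined)
    accuracy = (cm.tp + cm.tn) / cm.total
    f1 = f1_from(ppv, sens, undefined)
    return MetricsRow(
        run_id=run_id,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=accuracy,
        f1=f1,
        undefined=undefined,
    )


def f1_from(ppv: float, sensitivity: float, undefined: dict | None = None) -> float:
    """Harmonic mean of precision and recall."""
    if math.isnan(ppv) or math.isnan(sensitivity) or ppv + sensitivity == 0:
        if undefined is not None:
            undefined["f1"] = "ppv + sensitivity is zero or undefined"
        return math.nan
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def aggregate(rows: list[MetricsRow], ddof: int = 1) -> AggregateReport:
    """Mean, standard deviation (sample by default), min and max per metric.

    Undefined (NaN) per-run values are excluded metric-wise.
    """
    if len(rows) < 2:
        raise ParameterError("aggregation needs at least 2 rows (sd undefined otherwise)")
    mean, sd, lo, hi = {}, {}, {}, {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in rows], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            mean[m] = sd[m] = lo[m] = hi[m] = math.nan
            continue
        lo[m] = float(vals.min())
        hi[m] = float(vals.max())
        # clamp against last-ulp drift so min <= mean <= max holds exactly
        mean[m] = float(np.clip(vals.mean(), lo[m], hi[m]))
        sd[m] = float(vals.std(ddof=ddof))
    return AggregateReport(n_runs=len(rows), mean=mean, sd=sd, min=lo, max=hi)


def _fmt(x: float) -> str:
    return "" if (x is None or math.isnan(x)) else f"{round_half_away(x, 2):.2f}"


def _table_frame(
    rows: list[MetricsRow], report: AggregateReport, expected_runs: list[str] | None
) -> pd.DataFrame:
    if expected_runs is None:
        expected_runs = [f"{s}{i}" for s in "ABCDE" for i in range(1, 6)]
    present = {r.run_id for r in rows}
    absent = [r for r in expected_runs if r not in present]
    if absent:
        raise CompletenessError(f"missing runs: {absent}")
    ordered = sorted(rows, key=lambda r: expected_runs.index(r.run_id))
    records = [
        {"CNN": r.run_id, **{_DISPLAY_COLUMNS[m]: _fmt(getattr(r, m)) for m in METRIC_NAMES}}
        for r in ordered
    ]
    records.append({"CNN": "Mean", **{_DISPLAY_COLUMNS[m]: _fmt(report.mean[m]) for m in METRIC_NAMES}})
    records.append({"CNN": "SD", **{_DISPLAY_COLUMNS[m]: _fmt(report.sd[m]) for m in METRIC_NAMES}})
    return pd.DataFrame(records)


def render_table(
    rows: list[MetricsRow],
    report: AggregateReport,
    fmt: str = "csv",
    expected_runs: list[str] | None = None,
) -> str:
    """Render the per-run metric table plus Mean and SD rows.

    ``fmt`` is ``csv`` or ``markdown``.  Raises
    :class:`~octliver.exceptions.CompletenessError` when runs are missing.
    """
    df = _table_frame(rows, report, expected_runs)
    if fmt == "csv":
        buf = StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    if fmt == "markdown":
        header = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
        body = ["| " + " | ".join(str(v) for v in rec) + " |" for rec in df.itertuples(index=False)]
        return "\n".join([header, sep, *body]) + "\n"
    raise ParameterError(f"unknown table format {fmt!r}")


def parse_table_csv(text: str) -> pd.DataFrame:
    """Parse a rendered CSV table back into a DataFrame of strings."""
    return pd.read_csv(StringIO(text), dtype=str).fillna("")


def render_learning_curves(traces: dict, out_dir, plot: bool = True) -> list[Path]:
    """Write per-run learning curves as CSV (and PNG when ``plot``).

    ``traces`` maps run ids to :class:`octliver.classifier.EpochTrace`-like
    objects with ``train_loss``, ``val_loss``, ``train_f1``, ``val_f1``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for run_id, tr in sorted(traces.items()):
        df = pd.DataFrame(
            {
                "epoch": np.arange(1, len(tr.train_loss) + 1),
                "train_loss": tr.train_loss,
                "val_loss": tr.val_loss,
                "train_f1": tr.train_f1,
                "val_f1": tr.val_f1,
            }
        )
        csv_path = out_dir / f"learning_curve_{run_id}.csv"
        df.to_csv(csv_path, index=False)
        written.append(csv_path)
        if plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
            ax1.plot(df["epoch"], df["train_loss"], label="train")
            ax1.plot(df["epoch"], df["val_loss"], label="validation")
            ax1.set_xlabel("epoch"), ax1.set_ylabel("cross-entropy loss")
            ax1.legend()
            ax2.plot(df["epoch"], df["train_f1"], label="train")
            ax2.plot(df["epoch"], df["val_f1"], label="validation")
            ax2.set_xlabel("epoch"), ax2.set_ylabel("F1-score")
            ax2.set_ylim(0, 1.02)
            ax2.legend()
            fig.suptitle(f"Run {run_id}")
            fig.tight_layout()
            png_path = out_dir / f"learning_curve_{run_id}.png"
            fig.savefig(png_path, dpi=100)
            plt.close(fig)
            written.append(png_path)
    return written


def load_reference_runs() -> list[MetricsRow]:
    """Published per-run test-set metrics of a 25-model CV benchmark.

    Bundled as package data; used to validate the aggregation arithmetic
    against an independently computed summary.
    """
    with resources.files("octliver.data").joinpath("reference_runs.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        MetricsRow(
            run_id=rec.run_id,
            sensitivity=rec.sensitivity,
            specificity=rec.specificity,
            ppv=rec.ppv,
            npv=rec.npv,
            accuracy=rec.accuracy,
            f1=rec.f1,
        )
        for rec in df.itertuples(index=False)
    ]


__all__ = [
    "METRIC_NAMES",
    "ConfusionMatrix",
    "MetricsRow",
    "AggregateReport",
    "confusion",
    "metrics_from_cm",
    "f1_from",
    "aggregate",
    "render_table",
    "parse_table_csv",
    "render_learning_curves",
    "load_reference_runs",
]
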