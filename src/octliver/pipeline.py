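"""Convenience glue tying phantom/preprocess/split/classifier/metrics together."""

from __future__ import annotations

from . import classifier as clf
from . import metrics as mx
from .preprocess import PreprocParams, Tile, preprocess_cscan
from .split import SplitPlan


def preprocess_cohort(cohort, params: PreprocParams | None = None):
    """Preprocess every C-scan of a phantom cohort.

    ``cohort`` is a list of ``(RawCScan, GroundTruth, ScanMeta)`` triples.
    Returns ``(tiles, reports, surviving_metas)``; excluded C-scans
    contribute no tiles and are absent from ``surviving_metas``.
    """
    tiles: list[Tile] = []
    reports = []
    surviving = []
    for raw, _truth, meta in cohort:
        scan_tiles, report = preprocess_cscan(raw, params)
        tiles.extend(scan_tiles)
        reports.append(report)
        if not report.excluded:
            surviving.append(meta)
    return tiles, reports, surviving


def tiles_by_partition(tiles, plan: SplitPlan, run_id: str):
    """Split a tile list into (train, val, test) for one CV run."""
    run = plan.run(run_id)
    test_set = set(plan.test_scans)
    train_set = set(run.train_scans)
    val_set = set(run.val_scans)
    train = [t for t in tiles if t.scan_id in train_set]
    val = [t for t in tiles if t.scan_id in val_set]
    test = [t for t in tiles if t.scan_id in test_set]
    return train, val, test


def run_cv_iteration(tiles, plan: SplitPlan, run_id: str, config: clf.TrainConfig):
    """Train one CV run and evaluate it on the fixed test set.

    Returns ``(model, trace, metrics_row, (probabilities, predicted_labels))``.
    """
    train_tiles, val_tiles, test_tiles = tiles_by_partition(tiles, plan, run_id)
    model = clf.build_model(config)
    model, trace = clf.train(model, train_tiles, val_tiles, config)
    probs, labels = clf.predict(model, test_tiles, config)
    cm = mx.confusion([t.label for t in test_tiles], labels)
    row = mx.metrics_from_cm(cm, run_id=run_id)
    return model, trace, row, (probs, labels)


__all__ = ["preprocess_cohort", "tiles_by_partition", "run_cv_iteration"]
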