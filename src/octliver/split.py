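"""Leakage-safe stratified cross-validation planning at C-scan granularity.

The 70:15:15 protocol: a fixed, class-stratified 15% test set is drawn
first and set aside.  The remaining scans are then partitioned, within each
of 5 sets (A-E), into 5 class-stratified folds; iteration ``i`` of a set
uses fold ``i`` for validation and the other folds for training, giving 25
train/validation runs that all share the same test set.  C-scans are the
atomic unit: all tiles of one scan stay together in every partition, so
neighboring B-scans can never straddle training and validation.

The validation share of each run is a fifth of the retained 85% (17% of the
total), which matches the nominal 70:15 training/validation split only
approximately; the protocol trades that nicety for exactly disjoint
validation folds within a set.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InfeasibleSplitError, LeakageError, ParameterError
from .volume_io import LABELS, ScanMeta, round_half_away

PARTITIONS = ("train", "val", "test")


@dataclass(frozen=True)
class Run:
    set_label: str
    iteration: int
    train_scans: tuple[str, ...]
    val_scans: tuple[str, ...]

    @property
    def run_id(self) -> str:
        return f"{self.set_label}{self.iteration}"


@dataclass(frozen=True)
class SplitPlan:
    test_scans: tuple[str, ...]
    runs: tuple[Run, ...]
    seed: int
    labels: dict = field(default_factory=dict)  # scan_id -> class

    def run(self, run_id: str) -> Run:
        for r in self.runs:
            if r.run_id == run_id:
                return r
        raise KeyError(f"unknown run {run_id!r}")

    def partition_of(self, run: Run, scan_id: str) -> str:
        if scan_id in self.test_scans:
            return "test"
        if scan_id in run.train_scans:
            return "train"
        if scan_id in run.val_scans:
            return "val"
        raise KeyError(f"scan {scan_id!r} not in plan")

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "test_scans": list(self.test_scans),
            "labels": dict(self.labels),
            "runs": {
                r.run_id: {"train": list(r.train_scans), "val": list(r.val_scans)}
                for r in self.runs
            },
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        runs = tuple(
            Run(
                set_label=run_id[0],
                iteration=int(run_id[1:]),
                train_scans=tuple(spec["train"]),
                val_scans=tuple(spec["val"]),
            )
            for run_id, spec in sorted(payload["runs"].items())
        )
        return cls(
            test_scans=tuple(payload["test_scans"]),
            runs=runs,
            seed=int(payload["seed"]),
            labels=dict(payload.get("labels", {})),
        )


def _stratified_test_draw(
    by_class: dict[str, list[str]], test_frac: float, rng: np.random.Generator
) -> list[str]:
    test = []
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        n_test = max(1, int(round_half_away(test_frac * len(ids))))
        picked = rng.choice(len(ids), size=n_test, replace=False)
        test.extend(ids[i] for i in sorted(picked))
    return test


def make_split_plan(
    scans: list[ScanMeta],
    test_frac: float = 0.15,
    n_sets: int = 5,
    n_folds: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Build the fixed-test-set, 5x5 stratified CV plan.

    Per class, ``round(test_frac * n_class)`` scans (half away from zero,
    minimum one) go to the test set.  Within each set the remaining scans
    are shuffled with a set-specific seed and dealt round-robin into
    ``n_folds`` class-stratified folds.  The plan is a pure function of the
    scan list and the seed.
    """
    if not (0.0 < test_frac < 1.0):
        raise ParameterError("test_frac must be in (0, 1)")
    by_class: dict[str, list[str]] = {label: [] for label in LABELS}
    labels = {}
    for m in scans:
        # accept ScanMeta-like objects or (scan_id, label) mappings/tuples
        if hasattr(m, "scan_id"):
            sid, lab = m.scan_id, m.label
        elif isinstance(m, dict):
            sid, lab = m["scan_id"], m["label"]
        else:
            sid, lab = m
        if lab not in by_class:
            raise ParameterError(f"unknown class {lab!r} for scan {sid!r}")
        by_class[lab].append(sid)
        labels[sid] = lab
    for label, ids in by_class.items():
        if len(ids) < 2:
            raise InfeasibleSplitError(f"class {label!r} has fewer than 2 scans")
        if len(set(ids)) != len(ids):
            raise ParameterError(f"duplicate scan ids in class {label!r}")

    rng = np.random.default_rng(seed)
    test = _stratified_test_draw(by_class, test_frac, rng)
    test_set = set(test)
    remaining = {
        label: sorted(i for i in ids if i not in test_set)
        for label, ids in by_class.items()
    }
    for label, ids in remaining.items():
        if len(ids) < n_folds + 1:
            raise InfeasibleSplitError(
                f"class {label!r} has only {len(ids)} scans after the test draw; "
                f"needs at least {n_folds + 1} for {n_folds}-fold CV"
            )

    set_labels = string.ascii_uppercase[:n_sets]
    runs = []
    for s_idx, set_label in enumerate(set_labels):
        set_rng = np.random.default_rng(np.random.SeedSequence([seed, s_idx]))
        folds: list[list[str]] = [[] for _ in range(n_folds)]
        for label in sorted(remaining):
            ids = list(remaining[label])
            set_rng.shuffle(ids)
            for j, scan_id in enumerate(ids):
                folds[j % n_folds].append(scan_id)
        for i in range(n_folds):
            val = tuple(sorted(folds[i]))
            train = tuple(sorted(x for j, f in enumerate(folds) if j != i for x in f))
            runs.append(Run(set_label=set_label, iteration=i + 1, train_scans=train, val_scans=val))
    return SplitPlan(test_scans=tuple(sorted(test)), runs=tuple(runs), seed=seed, labels=labels)


def assign_tiles(plan: SplitPlan, manifest: pd.DataFrame) -> pd.DataFrame:
    """Expand a tile manifest into per-run partition assignments.

    The manifest needs ``tile_id`` and ``scan_id`` columns (``label``
    carried through when present).  Returns one row per (run, tile).
    """
    frames = []
    for run in plan.runs:
        df = manifest.copy()
        df["run_id"] = run.run_id
        df["partition"] = [plan.partition_of(run, s) for s in df["scan_id"]]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def verify_no_leakage(plan: SplitPlan, assignments: pd.DataFrame) -> pd.DataFrame:
    """Assert C-scan integrity of tile assignments against a plan.

    Every scan's tiles must map to exactly one partition per run, and that
    partition must agree with the plan.  Returns per-run tile counts by
    partition and class.  Scans of one patient may legally sit in different
    partitions: the unit of integrity is the C-scan.
    """
    required = {"tile_id", "scan_id", "run_id", "partition"}
    missing = required - set(assignments.columns)
    if missing:
        raise ParameterError(f"assignments missing columns: {sorted(missing)}")
    known = set(plan.test_scans) | {
        s for r in plan.runs for s in r.train_scans + r.val_scans
    }
    unknown = set(assignments["scan_id"]) - known
    if unknown:
        raise LeakageError(f"tiles reference scans absent from the plan: {sorted(unknown)}")
    for (run_id, scan_id), grp in assignments.groupby(["run_id", "scan_id"]):
        parts = set(grp["partition"])
        if len(parts) > 1:
            raise LeakageError(
                f"scan {scan_id!r} has tiles in partitions {sorted(parts)} of run {run_id}"
            )
        expected = plan.partition_of(plan.run(run_id), scan_id)
        if parts != {expected}:
            raise LeakageError(
                f"scan {scan_id!r} assigned to {parts.pop()!r} in run {run_id}, "
                f"plan says {expected!r}"
            )
    cols = ["run_id", "partition"]
    if "label" in assignments.columns:
        cols.append("label")
    counts = assignments.groupby(cols).size().rename("n_tiles").reset_index()
    return counts


__all__ = [
    "PARTITIONS",
    "Run",
    "SplitPlan",
    "make_split_plan",
    "assign_tiles",
    "verify_no_leakage",
]
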