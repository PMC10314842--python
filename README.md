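# octliver

Ex vivo optical coherence tomography (OCT) produces micrometre-resolution,
depth-resolved cross-sections of fresh liver resection specimens. Combined
with a convolutional neural network, it can tell colorectal liver
metastases (CRLM) apart from healthy liver parenchyma — a candidate
real-time adjunct to intraoperative frozen-section examination of resection
margins. `octliver` is a tested, reusable implementation of that analysis
pipeline for surgeons and imaging scientists working with SD-OCT volumes:

1. **phantom** — synthetic C-scan generator (tilted surface, exponential
   depth attenuation of the A-scan log-intensity, multiplicative gamma
   speckle, textural heterogeneity, detector-saturation column artifacts)
   with per-voxel ground truth, so every stage is testable without access
   to clinical data;
2. **volume_io** — an open C-scan container (16-bit PNG per B-scan +
   JSON metadata) and whole-C-scan 8-bit scaling anchored on the first,
   middle and last B-scans;
3. **preprocess** — saturated-column removal (column mean > image mean +
   *k*·std), tissue masking (5×5 median → binarize at gray value 20 →
   flood-fill/hole-fill → erosion/dilation → contour fill), overlapping
   299×299 tiling of the masked tissue, and the quality-control rules
   (a B-scan is flagged when ≥ 1/3 of its width is cropped or it yields no
   tiles; a C-scan is excluded when ≥ 1/3 of its B-scans are flagged);
4. **split** — leakage-safe 70:15:15 stratified cross-validation at C-scan
   granularity: one fixed 15% test set plus 5 sets (A–E) × 5 iterations of
   disjoint train/validation folds, 25 runs in total;
5. **classifier** — binary tile classifier with a grayscale tile replicated
   onto three input channels and a global-average-pooling → FC(1) → sigmoid
   head; trunks: `xception` (optional, needs torch) or `small_cnn`, a
   from-scratch NumPy CNN (< 10k parameters) that trains in minutes on one
   CPU. Mini-batch Adam, per-tile binary cross-entropy
   `L = −[y·log p + (1−y)·log(1−p)]`, per-epoch learning curves;
6. **metrics** — confusion matrices (positive class = tumor), sensitivity
   TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN),
   accuracy, F1 = harmonic mean of PPV and sensitivity, plus cross-run
   mean/SD/range aggregation and table/curve rendering.

A 25-run benchmark table of published per-run test-set metrics is bundled
as package data to validate the aggregation arithmetic.

## Worked example

```python
from octliver import classifier as clf, phantom as ph, pipeline
from octliver.preprocess import PreprocParams
from octliver.split import make_split_plan

cohort = ph.generate_cohort(10, seed=42)            # 20 C-scans, 32 B-scans each
tiles, reports, surviving = pipeline.preprocess_cohort(cohort, PreprocParams())
plan = make_split_plan([m for _, _, m in cohort], seed=42)
config = clf.small_cnn_config(seed=42)              # 5 epochs, lr 1e-3, batch 20
model, trace, row, _ = pipeline.run_cv_iteration(tiles, plan, "A1", config)
print(f"tiles: {len(tiles)}   test scans: {plan.test_scans}")
print("train loss:", [round(l, 4) for l in trace.train_loss])
print("test F1:", row.f1, " accuracy:", row.accuracy)
```

Output:

```
tiles: 1940   test scans: ('healthy_000', 'healthy_007', 'tumor_003', 'tumor_004')
train loss: [0.5789, 0.3868, 0.1021, 0.0217, 0.0088]
test F1: 1.0  accuracy: 1.0
```

The 20 phantom scans yield 1940 masked tiles; training loss falls
monotonically over the five epochs and the run classifies every test tile
of the four held-out C-scans correctly — the phantom classes (tumor
attenuates 1.6× faster and is 2.5× more heterogeneous) are deliberately
well separated.

The same flow is available from the shell:

```bash
octliver simulate   --out scans/ --n-per-class 13 --seed 7
octliver preprocess --in scans/ --out tiles/ --qc-report qc.csv
octliver split      --manifest tiles/manifest.csv --seed 7 --out plan.json
octliver train      --tiles tiles/ --plan plan.json --run A1 --out model_A1/
octliver predict    --model model_A1/ --tiles tiles/ --plan plan.json --out preds/preds_A1.csv
octliver evaluate   --preds preds/ --out report/
```

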