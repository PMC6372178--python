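# dcehist

Semiquantitative analysis of dynamic contrast-enhanced MRI (DCE-MRI) time
courses for differentiating prostate cancer from benign tissue, with
separate treatment of the transitional zone (TZ) and peripheral zone (PZ).

## The problem and the method

On DCE-MRI, prostate tumors and benign tissue differ in how fast and how
strongly they enhance after contrast injection — but in the TZ, benign
hyperplasia enhances as early and as strongly as cancer, so simple wash-in
measures fail there. `dcehist` implements a model-free, per-voxel
description of the enhancement time course that needs no arterial input
function and no pharmacokinetic model:

* **MWS (maximum wash-in slope)** — for each voxel, the maximum difference
  of the enhancement signal between two sequential time points, restricted
  to a 30 s window after the contrast inflow time (the first frame at
  which the whole-volume mean signal rises above its baseline level).
* **DPS (delay-phase slope)** — the slope of the enhancement from the
  terminal point of the MWS to the last acquired frame, capturing delayed
  wash-in and washout.

Signals are normalized per voxel to percent of the pre-contrast baseline,
so slopes are in percent-baseline per frame. Within circular regions of
interest of fixed physical diameter (7.5 and 10 mm), the per-voxel MWS and
DPS values form a histogram summarized by 14 first-order parameters: mean,
SD, CV, kurtosis (non-excess), skewness, IQR, P10/P25/P50/P75/P90, mFWHM
(width of the histogram at half of its peak count), P90−P10, and Range.

Cancer and benign ROIs are paired within patients, so group differences
use the Wilcoxon signed-rank test; parameters significant at the 10 mm
diameter go to ROC analysis with a Youden-index operating point
(J = sensitivity + specificity − 1) and Spearman correlation against the
Gleason score. The expected zonal pattern: PZ discrimination is carried by
wash-in amplitude (MWS mean and percentiles), TZ discrimination by the
delay-phase slope (DPS mean/percentiles, with cancer *lower*).

Because no patient data ships with the package, a synthetic 4D phantom
generator produces paired cohorts with the same statistical structure
(four tissue classes CTZ/NTZ/CPZ/NPZ, configurable kinetics and noise), so
the entire pipeline is testable end to end.

## Worked example

```python
import numpy as np
from dcehist import PhantomConfig, generate_cohort, slope_maps
from dcehist.pipeline import cohort_records, run_stats

config = PhantomConfig(seed=1)            # 16 TZ + 14 PZ patients
cohort = generate_cohort(config)

maps = slope_maps(cohort[0].series)       # per-voxel MWS/DPS of one patient
print(f"inflow frame: {maps.inflow_index}")

records = cohort_records(cohort)          # 14 parameters per ROI/diameter/map
report = run_stats(records)               # Wilcoxon + ROC + Spearman grid
for row in report["roc"]:
    if row["parameter"] == "mean":
        print(f"{row['zone']} {row['map']} mean: AUC {row['auc']:.3f}, "
              f"threshold {row['threshold']:.3f} ({row['direction']}), "
              f"sens {row['sensitivity']:.1f}% spec {row['specificity']:.1f}%")
```

Output:

```
inflow frame: 5
TZ DPS mean: AUC 0.859, threshold 0.346 (low), sens 75.0% spec 87.5%
PZ MWS mean: AUC 0.995, threshold 61.839 (high), sens 100.0% spec 92.9%
```

Contrast arrives at frame 5 of 25 (~50 s). In the transitional zone the
delay-phase slope separates cancer from benign tissue (cancer *low*,
AUC 0.86); in the peripheral zone the wash-in amplitude separates them
almost perfectly (cancer *high*, AUC 0.99) — the zonal pattern the method
is built to expose.

The same pipeline runs from the shell:

```
dcehist simulate --out-dir data --seed 1
dcehist extract  --data-dir data --out features.csv
dcehist stats    --features features.csv --out stats_report.json --tables-dir tables
```

and `dcehist reanalyze --raw table.xlsx --out report.json` recomputes the
statistics directly from an externally produced per-ROI histogram table
(XLSX or CSV; foreign column layouts adapt via `--column-map`).

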