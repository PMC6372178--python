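# Methods

This note records the model, the conventions, and the design choices made
where the procedure was genuinely open, in enough detail to reimplement
the package from scratch.

## Kinetic parameters

Each voxel's raw time course `S[k]` (25 frames, ~10 s apart by default) is
normalized to percent-of-baseline enhancement
`e[k] = 100 (S[k] − S0)/S0`, with `S0` the mean of the pre-contrast
frames (default 3; contrast is injected at the start of the fourth
measurement). Voxels with `S0 ≤ 0` are invalid and appear as missing in
every downstream map. A raw-signal mode (`normalization="raw"`) computes
slopes on `S` directly; it is strictly offset-invariant and is provided
because slope units in this family of semiquantitative analyses are often
left unstated. The default is normalized, which makes slopes comparable
across coils and gains.

**Inflow time** is detected once per series, not per voxel: the
whole-volume mean signal is computed per frame, and the inflow frame is
the first frame at or after the baseline block exceeding
`baseline mean + k_sigma · baseline SD` (`k_sigma = 3`, SD floored at
1e-6 so a noiseless baseline still yields a positive threshold). A series
whose volume mean never crosses the threshold is rejected as unusable
(`NoInflowError`), mirroring the exclusion of corrupted acquisitions.

**MWS** is the maximum difference between two sequential time points,
`e[i+1] − e[i]`, over pairs whose later point lies no more than 30 s after
the inflow frame (inclusive boundary) and no earlier than the inflow
frame itself — the pair straddling the onset is eligible and usually
carries the largest jump. Ties take the earliest pair. The slope
denominator is one frame (a plain sequential difference); frame times are
recorded, so per-second slopes are derivable. The frame index of the
maximizing pair's later point is the **MWS terminal index**.

**DPS** defaults to the two-point slope
`(e[last] − e[terminal]) / (last − terminal)` in percent-baseline per
frame; endpoint-to-endpoint is the natural reading of "slope from the
terminal point to the end of the time course". An OLS mode (least-squares
slope of `e` against frame index over `[terminal, last]`) is provided as a
robustness option. A voxel whose terminal point is the last frame has no
delay phase and is missing on the DPS map.

## ROI geometry

ROIs are in-plane circles of fixed physical diameter (7.5 and 10 mm by
default), one malignant and one benign per patient in the same scan
plane. A voxel belongs to the mask when its **center** lies within
`diameter/2` of the center voxel's center, measured in millimetres
(anisotropic pixel spacing respected). Center-in-circle is the simplest
deterministic inclusion rule; partial-coverage weighting was deliberately
not implemented. Pixel spacing always comes from the image header.
Missing voxels inside a mask are dropped and counted; an ROI with more
than 10% missing voxels (configurable) is rejected, and a fully missing
ROI is an error.

## Histogram parameters

The 14 first-order parameters use these conventions:

* SD is the sample estimate (n−1); CV = SD/mean per ROI, with **no**
  winsorization — when the mean is near zero (typical for DPS) CV is
  wildly unstable, and that instability is preserved deliberately because
  group summaries average per-ROI CVs.
* Kurtosis is moment-based and **non-excess** (normal → 3); skewness is
  moment-based. Both are missing for zero-SD samples, CV also when the
  mean is zero. An all-equal sample is treated as exactly degenerate even
  when float cancellation would report an SD of ~1e-16.
* Percentiles interpolate linearly between order statistics (the common
  scientific-software default; configurable). IQR = P75−P25 and
  P90P10 = P90−P10 hold exactly by construction.
* **mFWHM**: the sample is binned (Freedman–Diaconis, falling back to 10
  bins when the IQR is zero, capped at 512 bins against pathological
  dynamic ranges); the width is the distance between the outermost left
  and right crossings of half the peak bin count, each crossing linearly
  interpolated between bin centers. The outermost-crossing rule makes the
  width span both modes of a bimodal histogram. The estimator is
  validated against the Gaussian closed form FWHM = 2√(2 ln 2)·SD ≈
  2.3548·SD; at n = 1e5 it lands within ~4% of that limit (slightly low,
  because interpolating between bin centers clips roughly half a bin on
  each flank).
* A sample needs at least 5 values (configurable) after missing removal.

## Group statistics

Cancer/benign comparisons use the two-sided Wilcoxon signed-rank test on
complete within-patient pairs: zero differences are dropped, the exact
null distribution is used for n ≤ 25 without ties in |differences|, and
the tie-corrected normal approximation with continuity correction
otherwise. Incomplete pairs and pairs with missing parameter values are
dropped and logged. No multiple-testing correction is applied to the
primary output (raw p-values, alpha = 0.05); a Benjamini–Hochberg column
is available behind a flag and is explicitly labelled an extension.

ROC analysis runs for parameters significant at the 10 mm diameter. AUC
uses the rank-sum (Mann–Whitney) formulation with half credit for ties,
oriented so AUC ≥ 0.5; the discriminating polarity (cancer-high vs
cancer-low) is auto-detected and reported, since e.g. TZ cancer has
*lower* CV and DPS than benign tissue. Candidate thresholds are midpoints
between adjacent distinct pooled values; the reported threshold maximizes
the Youden index J = sensitivity + specificity − 1, with ties broken by
higher sensitivity, then lower threshold. Sensitivity, specificity and
accuracy are percentages at that threshold. No AUC confidence intervals
and no cross-validation: the analysis reports apparent performance only.

Spearman correlation (tie-aware, t-approximation p) relates each
significant parameter to the Gleason score of the cancer ROIs. The score
can be used as the recorded sum (default) or mapped to ordinal grade
groups; sums cannot distinguish 3+4 from 4+3, so the grade-group mapping
is approximate.

## Synthetic phantoms

Each simulated patient is a 4D series (default 3 slices × 48 × 48 × 25
frames, 3.2 mm slices, 0.9375 mm pixels, 10 s frames) containing two
non-overlapping 14 mm disk lesions in the central slice — one cancer, one
benign, same zone — in a modestly enhancing background. Enhancement
follows

    e(t) = A (1 − exp(−k (t − t0))) + d · max(0, (t − t0)/dt − n_fast)

a fast exponential wash-in (amplitude `A` percent, rate `k`/s) plus a
linear delay phase (`d` percent per frame) beginning `n_fast = 3` frames
after onset (`t0` = frame 4, one frame after injection). Raw signal is
`S0 (1 + e/100)` plus Gaussian noise of SD `noise_sd` percent of `S0`
(default 1.5%). Gaussian rather than Rician noise is a documented
simplification: at this SNR the slopes operate far above the noise floor.

Per-patient kinetics are drawn from class distributions chosen to encode
the zonal contrasts the analysis targets:

| class | A (%)    | k (/s)      | d (%/frame) |
|-------|----------|-------------|-------------|
| CPZ   | 90 ± 15  | 0.35 ± 0.05 | 0.12 ± 0.15 |
| NPZ   | 40 ± 12  | 0.25 ± 0.05 | 0.26 ± 0.15 |
| CTZ   | 85 ± 15  | 0.30 ± 0.05 | 0.15 ± 0.20 |
| NTZ   | 85 ± 15  | 0.30 ± 0.05 | 0.45 ± 0.20 |

PZ cancer enhances more strongly and faster than normal PZ; CTZ and NTZ
share their wash-in distribution and differ only in the delay slope
(cancer lower). The wash-in rates are fast enough that the exponential
phase is nearly complete within two frames, which keeps the delay phase
clean for parameter recovery: with zero noise, per-voxel DPS equals the
configured `d` up to a closed-form truncation term
`A·exp(−k Δt_term)/n_intervals` plus the fast-phase frames not yet
accumulating the linear slope. A consequence of the fast rates is that
synthetic MWS magnitudes (~0.95·A, i.e. tens of percent per frame) sit
above the wash-in slopes typical of clinical prostate series; the
phantom's purpose is effect *structure* (directions, pairing, AUCs), not
absolute slope calibration.

Gleason scores are tied to the sampled kinetics (TZ: thresholding `d`,
lower slope → grade 7 vs 6; PZ: amplitude quantiles → 7/8/9) so the
Spearman analysis has a nonzero signal to find.

The default cohort is 16 TZ + 14 PZ patients — 60 ROIs per diameter —
matching the pairing structure the statistics assume. Determinism: the
master seed spawns one RNG stream per patient; kinetic draws precede the
noise field, and the noise field is drawn at unit variance and scaled by
`noise_sd`, so cohorts at different noise levels share all other
randomness (common random numbers). Noise degradation of the TZ
delay-slope AUC is checked over a fixed block of 3 seeds × noise levels
{0, 20, 60}% because a single 16-pair cohort's AUC has sampling noise of
the same order as the degradation between adjacent levels.

What the phantoms do **not** model: anatomy (no prostate shape, no zonal
geometry), T1 saturation and contrast-agent physics, coil profiles,
motion, Rician noise, and within-lesion kinetic heterogeneity beyond
voxel noise. Passing tests therefore demonstrate the correctness of the
extraction and statistics machinery and the detectability of the
configured effect structure — not clinical performance on real data.

## Problem sizes and tolerances

Property tests run on vectors of 5–200 values; the mFWHM Gaussian limit
uses 1e5 draws with a 5% relative tolerance; exact Wilcoxon tests are
checked against full 2^n sign enumeration up to n = 12; AUC and Youden
optimality against brute-force enumeration at group sizes ≤ 12 + 12;
cohort-level checks use the full default cohort (30 patients) and 3
replicate seeds. The complete suite runs in well under a minute.

## Known limitations

* The "modified" step of the mFWHM found in parts of the radiomics
  literature is not standardized; the definition here (outermost
  interpolated half-maximum crossings of an FD-binned histogram) is an
  explicit, validated choice, and other software may differ by a few
  percent on the same sample.
* The Wilcoxon signed-rank p is invariant under common positive affine
  transforms of both paired vectors, but not under arbitrary monotone
  transforms (those can reorder absolute differences); tests assert the
  affine case.
* Exact-vs-asymptotic Wilcoxon variants differ in the third decimal of p
  near the significance boundary; the variant used (exact for n ≤ 25
  without ties) is fixed and documented rather than configurable.
* The reanalysis mode expects one row per (patient, tissue label,
  diameter, map) with the 14 canonical parameter columns; foreign layouts
  must be adapted via the column-mapping config, not guessed.
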