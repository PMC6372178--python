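"""First-order histogram parameters of a per-voxel value sample.

The 14 parameters characterizing the within-ROI distribution of a slope
map: mean, SD (sample, n-1), CV, kurtosis, skewness, IQR, the P10/P25/
P50/P75/P90 percentiles, mFWHM, P90-P10, and Range (max - min).

Conventions fixed here and used throughout:

* kurtosis is the NON-excess moment-based estimate (normal -> 3);
* skewness is the moment-based estimate;
* percentiles use linear interpolation between order statistics
  (configurable);
* CV is per-sample (sd/mean) with no winsorization, so values are unstable
  when the mean is near zero — deliberately left as-is;
* mFWHM is the width of the value histogram at half of its peak count,
  with outermost half-maximum crossings interpolated between bin centers;
  for a normal sample it converges to ``2 * sqrt(2 ln 2) * SD = 2.3548 SD``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientSampleError, ValidationError
from .io import FEATURE_NAMES

#: FWHM of a unit-SD Gaussian: 2*sqrt(2*ln 2).
GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class HistogramFeatures:
    """The 14 first-order histogram parameters of one value sample."""

    mean: float
    sd: float
    cv: float
    kurtosis: float
    skewness: float
    iqr: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float
    mfwhm: float
    p90p10: float
    range: float
    n: int = 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


#: Hard cap on histogram bins; guards against pathological samples whose
#: IQR is orders of magnitude smaller than their range.
MAX_BINS = 512


def _freedman_diaconis_bins(values: np.ndarray, fallback_bins: int = 10) -> int:
    """Freedman-Diaconis bin count with a fallback when IQR = 0."""
    n = values.size
    iqr = float(np.percentile(values, 75) - np.percentile(values, 25))
    span = float(values.max() - values.min())
    if iqr <= 0 or span <= 0:
        return fallback_bins
    width = 2.0 * iqr / n ** (1.0 / 3.0)
    return min(MAX_BINS, max(1, int(math.ceil(span / width))))


def _half_max_crossing(centers: np.ndarray, counts: np.ndarray, half: float,
                       from_left: bool) -> float:
    """Outermost crossing of ``half`` between bin centers.

    Scanning from the chosen side, finds the first bin whose count reaches
    ``half`` and interpolates the crossing position linearly between that
    bin's center and its outward neighbour's.
    """
    order = range(counts.size) if from_left else range(counts.size - 1, -1, -1)
    for j in order:
        if counts[j] >= half:
            outward = j - 1 if from_left else j + 1
            if outward < 0 or outward >= counts.size:
                return float(centers[j])
            c_out, c_in = counts[outward], counts[j]
            if c_in == c_out:
                return float(centers[j])
            frac = (half - c_out) / (c_in - c_out)
            return float(centers[outward] + frac * (centers[j] - centers[outward]))
    raise AssertionError("no bin reaches half of the maximum count")


def mfwhm(values: np.ndarray, binning: str | int = "fd") -> float:
    """Modified full width at half maximum of the value histogram.

    Bins the sample (Freedman-Diaconis by default, falling back to 10 bins
    when the IQR is zero; an integer forces that bin count), locates the
    peak bin count, and returns the distance between the outermost left
    and right crossings of half the peak, each linearly interpolated
    between bin centers. A degenerate (zero-SD) sample has width 0.
    """
    values = np.asarray(values, dtype=float)
    if values.max() == values.min():  # degenerate sample: zero-width histogram
        return 0.0
    if binning == "fd":
        nbins = _freedman_diaconis_bins(values)
    elif isinstance(binning, int):
        nbins = binning
    else:
        raise ValidationError(f"unknown binning rule {binning!r}")
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    half = counts.max() / 2.0
    left = _half_max_crossing(centers, counts, half, from_left=True)
    right = _half_max_crossing(centers, counts, half, from_left=False)
    return float(right - left)


def compute_features(
    values: np.ndarray,
    min_n: int = 5,
    percentile_method: str = "linear",
    binning: str | int = "fd",
) -> HistogramFeatures:
    """Compute all 14 histogram parameters of a value sample.

    NaNs are removed first; fewer than ``min_n`` remaining values raise
    :class:`InsufficientSampleError`. CV is missing (NaN) when the mean or
    SD is zero; skewness and kurtosis are missing when the SD is zero.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = values.size
    if n < min_n:
        raise InsufficientSampleError(f"need at least {min_n} values, got {n}")

    mean = float(np.mean(values))
    # an all-equal sample is exactly degenerate even when float cancellation
    # in the moment computation would report a ~1e-16 SD
    sd = 0.0 if values.max() == values.min() else float(np.std(values, ddof=1))
    p10, p25, p50, p75, p90 = (
        float(np.percentile(values, q, method=percentile_method)) for q in (10, 25, 50, 75, 90)
    )
    if sd == 0.0:
        cv = skewness = kurtosis = float("nan")
    else:
        cv = sd / mean if mean != 0.0 else float("nan")
        with warnings.catch_warnings():
            # scipy warns on near-constant data; NaN results are acceptable there
            warnings.simplefilter("ignore", RuntimeWarning)
            skewness = float(stats.skew(values, bias=True))
            kurtosis = float(stats.kurtosis(values, fisher=False, bias=True))
    return HistogramFeatures(
        mean=mean,
        sd=sd,
        cv=cv,
        kurtosis=kurtosis,
        skewness=skewness,
        iqr=p75 - p25,
        p10=p10,
        p25=p25,
        p50=p50,
        p75=p75,
        p90=p90,
        mfwhm=mfwhm(values, binning=binning),
        p90p10=p90 - p10,
        range=float(values.max() - values.min()),
        n=n,
    )
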