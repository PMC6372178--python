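"""Model-free kinetic parameters of the dynamic time course.

For every voxel the pipeline extracts two semiquantitative slopes:

* **MWS** (maximum wash-in slope) — the maximum difference between two
  sequential time points, restricted to a 30 s window after the contrast
  inflow time.
* **DPS** (delay-phase slope) — the slope from the terminal point of the
  MWS to the last time point of the acquisition; it captures delayed
  wash-in and washout behaviour.

The inflow time is detected once per series from the whole-volume mean
signal (onset of signal increase above the baseline level). No
pharmacokinetic model and no arterial input function are involved, which
is the point: these parameters are robust to AIF and model-selection
effects.

Units: by default signals are normalized to percent of the voxel's
pre-contrast baseline, and slopes are per frame (plain sequential
differences). A raw-signal mode is available; per-second slopes are
derivable from the recorded frame times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, InvalidVoxelError, NoInflowError
from .io import DynamicSeries

__all__ = [
    "VoxelTimeCourse",
    "SlopeMaps",
    "normalize_to_baseline",
    "detect_inflow",
    "compute_mws",
    "compute_dps",
    "slope_maps",
]

#: Floor applied to the baseline SD so a noiseless baseline still yields a
#: positive inflow threshold.
BASELINE_SD_FLOOR = 1e-6


@dataclass(frozen=True)
class VoxelTimeCourse:
    """Enhancement values of one voxel per frame, with frame times."""

    enhancement: np.ndarray
    times_s: np.ndarray

    def __post_init__(self) -> None:
        enh = np.asarray(self.enhancement, dtype=float)
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "enhancement", enh)
        object.__setattr__(self, "times_s", t)
        if enh.shape != t.shape or enh.ndim != 1:
            raise ValueError("enhancement and times_s must be 1D of equal length")


@dataclass(frozen=True)
class SlopeMaps:
    """Per-voxel MWS and DPS maps.

    ``mws`` and ``dps`` are 3D float maps (NaN = invalid/missing voxel);
    ``mws_terminal_index`` is a 3D int map (-1 = missing); ``inflow_index``
    is the single, series-global contrast-arrival frame.
    """

    mws: np.ndarray
    dps: np.ndarray
    inflow_index: int
    mws_terminal_index: np.ndarray


def normalize_to_baseline(
    raw: np.ndarray,
    n_baseline_frames: int,
    times_s: np.ndarray | None = None,
) -> VoxelTimeCourse:
    """Convert a raw voxel time course to percent-of-baseline enhancement.

    ``enhancement[k] = 100 * (S[k] - S0) / S0`` with S0 the mean of the
    first ``n_baseline_frames`` values. Raises :class:`InvalidVoxelError`
    when S0 <= 0 (the voxel is excluded from the maps as missing).
    """
    raw = np.asarray(raw, dtype=float)
    if times_s is None:
        times_s = np.arange(raw.size, dtype=float)
    s0 = float(np.mean(raw[:n_baseline_frames]))
    if not s0 > 0:
        raise InvalidVoxelError(f"non-positive baseline mean {s0}")
    return VoxelTimeCourse(100.0 * (raw - s0) / s0, times_s)


def detect_inflow(series: DynamicSeries, k_sigma: float = 3.0) -> int:
    """Detect the contrast inflow frame from the whole-volume mean signal.

    The onset of signal increase is the first frame at or after the
    baseline block whose whole-volume mean exceeds
    ``baseline mean + k_sigma * baseline SD`` (SD floored at
    :data:`BASELINE_SD_FLOOR`). Returns that frame index, global for the
    series.
    """
    nb = series.n_baseline_frames
    if series.n_frames < nb + 2:
        raise ConfigurationError(
            f"series needs at least {nb + 2} frames, has {series.n_frames}"
        )
    trace = np.nanmean(series.signal.reshape(-1, series.n_frames), axis=0)
    base_mean = float(np.mean(trace[:nb]))
    base_sd = float(np.std(trace[:nb], ddof=1))
    threshold = base_mean + k_sigma * max(base_sd, BASELINE_SD_FLOOR)
    above = np.nonzero(trace[nb:] > threshold)[0]
    if above.size == 0:
        raise NoInflowError(
            f"whole-volume mean never exceeds {threshold:.6g} "
            f"(baseline {base_mean:.6g} +/- {base_sd:.6g}); series unusable"
        )
    return nb + int(above[0])


def _eligible_pair_ends(times_s: np.ndarray, inflow_index: int, window_s: float) -> np.ndarray:
    """Frame indices j such that the sequential pair (j-1, j) is eligible
    for the MWS search: j >= inflow and times[j] <= times[inflow] + window.

    The pair straddling the onset, (inflow-1, inflow), is eligible; a pair
    whose later point lands exactly at inflow time + window is eligible
    (inclusive boundary).
    """
    j = np.arange(1, times_s.size)
    mask = (j >= inflow_index) & (times_s[j] <= times_s[inflow_index] + window_s)
    return j[mask]


def compute_mws(
    tc: VoxelTimeCourse, inflow_index: int, window_s: float = 30.0
) -> tuple[float, int]:
    """Maximum wash-in slope of one voxel.

    Returns ``(mws, terminal_index)``: the maximum difference between two
    sequential time points among eligible pairs, and the later frame index
    of the pair achieving it (earliest on ties).
    """
    if not 0 <= inflow_index < tc.times_s.size:
        raise ConfigurationError(f"inflow_index {inflow_index} out of range")
    ends = _eligible_pair_ends(tc.times_s, inflow_index, window_s)
    if ends.size == 0:
        raise ConfigurationError(
            f"no eligible sequential pair within {window_s} s of inflow; "
            "window shorter than one frame interval"
        )
    diffs = tc.enhancement[ends] - tc.enhancement[ends - 1]
    best = int(np.argmax(diffs))  # argmax returns the first maximum: earliest pair
    return float(diffs[best]), int(ends[best])


def compute_dps(tc: VoxelTimeCourse, terminal_index: int, mode: str = "two_point") -> float:
    """Delay-phase slope from the MWS terminal point to the last frame.

    ``two_point`` (default): endpoint-to-endpoint slope in percent-baseline
    per frame interval. ``ols``: least-squares slope of enhancement vs
    frame index over ``[terminal, last]``. Returns NaN when the terminal
    point is the last frame (undefined; the voxel is missing on the map).
    """
    last = tc.enhancement.size - 1
    if terminal_index >= last:
        return float("nan")
    if mode == "two_point":
        return float(
            (tc.enhancement[last] - tc.enhancement[terminal_index]) / (last - terminal_index)
        )
    if mode == "ols":
        x = np.arange(terminal_index, last + 1, dtype=float)
        y = tc.enhancement[terminal_index : last + 1]
        xc = x - x.mean()
        return float(xc @ (y - y.mean()) / (xc @ xc))
    raise ConfigurationError(f"unknown dps mode {mode!r}")


def slope_maps(
    series: DynamicSeries,
    k_sigma: float = 3.0,
    window_s: float = 30.0,
    dps_mode: str = "two_point",
    normalization: str = "percent_baseline",
) -> SlopeMaps:
    """Compute MWS and DPS maps for a whole series (vectorized).

    Equivalent to running :func:`normalize_to_baseline`,
    :func:`compute_mws` and :func:`compute_dps` on every voxel, with the
    inflow frame detected once globally. ``normalization`` is
    ``"percent_baseline"`` (default) or ``"raw"`` (slopes in raw scanner
    units; strictly offset-invariant). Invalid voxels (non-positive
    baseline in normalized mode) are NaN in both maps.
    """
    if normalization not in ("percent_baseline", "raw"):
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    if dps_mode not in ("two_point", "ols"):
        raise ConfigurationError(f"unknown dps mode {dps_mode!r}")

    inflow = detect_inflow(series, k_sigma=k_sigma)
    nb = series.n_baseline_frames
    signal = np.asarray(series.signal, dtype=float)
    s0 = signal[..., :nb].mean(axis=-1)

    if normalization == "percent_baseline":
        valid = s0 > 0
        safe_s0 = np.where(valid, s0, 1.0)
        enh = 100.0 * (signal - safe_s0[..., None]) / safe_s0[..., None]
    else:
        valid = np.ones(s0.shape, dtype=bool)
        enh = signal - s0[..., None]  # sequential differences equal raw differences

    times = series.frame_times_s
    ends = _eligible_pair_ends(times, inflow, window_s)
    if ends.size == 0:
        raise ConfigurationError(
            f"no eligible sequential pair within {window_s} s of inflow"
        )
    diffs = enh[..., ends] - enh[..., ends - 1]
    best = np.argmax(diffs, axis=-1)  # first maximum: earliest pair on ties
    mws = np.take_along_axis(diffs, best[..., None], axis=-1)[..., 0]
    terminal = ends[best]

    last = series.n_frames - 1
    denom = last - terminal
    enh_term = np.take_along_axis(enh, terminal[..., None], axis=-1)[..., 0]
    if dps_mode == "two_point":
        with np.errstate(divide="ignore", invalid="ignore"):
            dps = np.where(denom > 0, (enh[..., last] - enh_term) / np.maximum(denom, 1), np.nan)
    else:
        dps = np.full(s0.shape, np.nan)
        for t in np.unique(terminal):
            sel = terminal == t
            if t >= last:
                continue
            x = np.arange(t, last + 1, dtype=float)
            xc = x - x.mean()
            y = enh[sel, t : last + 1]
            dps[sel] = (y - y.mean(axis=-1, keepdims=True)) @ xc / (xc @ xc)

    mws = np.where(valid, mws, np.nan)
    dps = np.where(valid & (denom > 0), dps, np.nan)
    terminal_map = np.where(valid, terminal, -1).astype(int)
    return SlopeMaps(mws=mws, dps=dps, inflow_index=inflow, mws_terminal_index=terminal_map)
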