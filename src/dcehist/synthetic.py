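"""Synthetic 4D dynamic-contrast phantoms with paired tissue-class regions.

Each simulated patient is one 4D series containing two circular lesions in
a uniformly enhancing background: one cancer and one benign region of the
same prostate zone, mirroring the paired ROI selection of the study
design. Voxel enhancement follows a fast exponential wash-in followed by a
linear delay phase,

    e(t) = A * (1 - exp(-k * (t - t0))) + d * max(0, (t - t0)/dt - n_fast)

with amplitude ``A`` (percent of baseline), wash-in rate ``k`` (per
second), delay-phase slope ``d`` (percent-baseline per frame), contrast
onset ``t0`` and frame interval ``dt``. Raw signal is
``S0 * (1 + e/100)`` plus Gaussian noise of SD ``noise_sd`` percent of
baseline.

The default class parameters encode the zonal contrasts the analysis is
designed to detect: peripheral-zone cancer enhances more strongly and
faster than normal peripheral tissue (discrimination carried by wash-in
amplitude), while transitional-zone cancer shares the benign wash-in
amplitude but has a smaller delay-phase slope (discrimination carried by
DPS). Noise is Gaussian, not Rician: at the simulated SNR the slopes
operate far above the noise floor, so the Rician bias is negligible.

Determinism: the same seed reproduces the cohort bit-for-bit. Kinetic
parameters and a unit-variance noise field are drawn in a fixed order and
the noise field is scaled by ``noise_sd`` afterwards, so cohorts generated
at different noise levels from the same seed share all random draws
(common random numbers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import LayoutError, ValidationError
from .io import (
    DynamicSeries,
    RoiSpec,
    write_dynamic_series,
    write_roi_specs,
)
from .roi import circular_mask

__all__ = [
    "TissueClassKinetics",
    "PhantomConfig",
    "PatientPhantom",
    "class_curve",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class TissueClassKinetics:
    """Population distribution of the kinetic parameters of one tissue class.

    ``amplitude`` in percent of baseline (truncated at 0 when sampled),
    ``rate`` per second, ``delay_slope`` in percent-baseline per frame;
    ``onset_frame`` is the frame index at which contrast arrives.
    """

    amplitude_mean: float
    amplitude_sd: float
    rate_mean: float
    rate_sd: float
    delay_slope_mean: float
    delay_slope_sd: float
    onset_frame: int = 4

    def sample(self, rng: np.random.Generator) -> tuple[float, float, float]:
        """Draw one (amplitude, rate, delay_slope) triple; amplitude and
        rate are truncated at 0."""
        a = max(0.0, rng.normal(self.amplitude_mean, self.amplitude_sd))
        k = max(1e-3, rng.normal(self.rate_mean, self.rate_sd))
        d = rng.normal(self.delay_slope_mean, self.delay_slope_sd)
        return a, k, d


def _default_classes() -> dict[str, TissueClassKinetics]:
    # PZ: cancer enhances more strongly/faster than normal tissue.
    # TZ: cancer and normal share the wash-in amplitude; cancer has the
    # smaller delay-phase slope (0.15 vs 0.45 percent/frame).
    return {
        "CPZ": TissueClassKinetics(90.0, 15.0, 0.35, 0.05, 0.12, 0.15),
        "NPZ": TissueClassKinetics(40.0, 12.0, 0.25, 0.05, 0.26, 0.15),
        "CTZ": TissueClassKinetics(85.0, 15.0, 0.30, 0.05, 0.15, 0.20),
        "NTZ": TissueClassKinetics(85.0, 15.0, 0.30, 0.05, 0.45, 0.20),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of the synthetic cohort.

    Acquisition constants default to the study protocol: 25 dynamic
    frames, ~10 s temporal resolution, contrast injected after the third
    measurement (3 baseline frames), 3.2 mm slices with ~0.94 mm in-plane
    pixels. ``seed`` is mandatory for reproducibility.
    """

    seed: int
    grid_shape: tuple[int, int, int] = (3, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (3.2, 0.9375, 0.9375)
    n_frames: int = 25
    frame_interval_s: float = 10.0
    n_baseline_frames: int = 3
    fast_phase_frames: int = 3
    noise_sd: float = 1.5
    baseline_signal: float = 200.0
    region_diameter_mm: float = 14.0
    roi_diameters_mm: tuple[float, ...] = (7.5, 10.0)
    n_tz_patients: int = 16
    n_pz_patients: int = 14
    classes: dict[str, TissueClassKinetics] = field(default_factory=_default_classes)
    background: TissueClassKinetics = TissueClassKinetics(30.0, 0.0, 0.25, 0.0, 0.20, 0.0)


@dataclass(frozen=True)
class PatientPhantom:
    """One simulated patient: series, paired ROI specs, ground truth."""

    patient_id: str
    zone: str
    series: DynamicSeries
    roi_specs: list[RoiSpec]
    ground_truth: dict


def class_curve(
    amplitude: float,
    rate: float,
    delay_slope: float,
    times_s: np.ndarray,
    onset_time_s: float,
    frame_interval_s: float,
    fast_phase_frames: int = 3,
) -> np.ndarray:
    """Closed-form enhancement curve: exponential wash-in + linear delay phase.

    Zero before onset; afterwards ``A*(1-exp(-k*(t-t0)))`` plus
    ``d`` percent per frame accumulated beyond the fast phase
    (``fast_phase_frames`` frame intervals after onset).
    """
    t = np.asarray(times_s, dtype=float)
    dt_onset = t - onset_time_s
    wash_in = amplitude * (1.0 - np.exp(-rate * np.clip(dt_onset, 0.0, None)))
    linear = delay_slope * np.clip(dt_onset / frame_interval_s - fast_phase_frames, 0.0, None)
    return np.where(dt_onset > 0, wash_in + linear, 0.0)


def _region_centers(config: PhantomConfig) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    ns, nr, nc = config.grid_shape
    sl = ns // 2
    return (sl, nr // 2, nc // 4), (sl, nr // 2, 3 * nc // 4)


def generate_phantom(
    config: PhantomConfig,
    patient_id: str = "P01",
    zone: str = "TZ",
    rng: np.random.Generator | None = None,
) -> PatientPhantom:
    """Generate one patient's 4D series with a cancer and a benign region.

    The two regions are disks of ``region_diameter_mm`` placed in the
    central slice; overlapping or out-of-bounds regions raise
    :class:`LayoutError`. ROI specs are emitted at every configured
    diameter for both regions. Identical seeds give bit-identical output.
    """
    if zone not in ("TZ", "PZ"):
        raise ValidationError(f"zone must be TZ or PZ, got {zone!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cancer_label, benign_label = ("CTZ", "NTZ") if zone == "TZ" else ("CPZ", "NPZ")
    center_cancer, center_benign = _region_centers(config)

    plane_shape = config.grid_shape[1:]
    spacing_rc = (config.voxel_spacing_mm[1], config.voxel_spacing_mm[2])
    try:
        mask_cancer = circular_mask(center_cancer[1:], config.region_diameter_mm, spacing_rc,
                                    shape=plane_shape)
        mask_benign = circular_mask(center_benign[1:], config.region_diameter_mm, spacing_rc,
                                    shape=plane_shape)
    except Exception as err:
        raise LayoutError(f"phantom region does not fit the grid: {err}") from err
    sep_mm = np.hypot(
        (center_cancer[1] - center_benign[1]) * spacing_rc[0],
        (center_cancer[2] - center_benign[2]) * spacing_rc[1],
    )
    if sep_mm < config.region_diameter_mm:
        raise LayoutError(
            f"regions {sep_mm:.1f} mm apart overlap at diameter {config.region_diameter_mm} mm"
        )

    times = np.arange(config.n_frames, dtype=float) * config.frame_interval_s

    # fixed draw order: cancer kinetics, benign kinetics, then the noise field
    kin_cancer = config.classes[cancer_label].sample(rng)
    kin_benign = config.classes[benign_label].sample(rng)
    unit_noise = rng.standard_normal(config.grid_shape + (config.n_frames,))

    def curve(kin: tuple[float, float, float], cls: TissueClassKinetics) -> np.ndarray:
        onset_t = times[cls.onset_frame]
        return class_curve(*kin, times, onset_t, config.frame_interval_s,
                           config.fast_phase_frames)

    bg = config.background
    bg_curve = curve((bg.amplitude_mean, bg.rate_mean, bg.delay_slope_mean), bg)
    enh = np.broadcast_to(bg_curve, config.grid_shape + (config.n_frames,)).copy()
    for (sl, _, _), mask, kin, cls_name in (
        (center_cancer, mask_cancer, kin_cancer, cancer_label),
        (center_benign, mask_benign, kin_benign, benign_label),
    ):
        enh[sl, mask[:, 0], mask[:, 1], :] = curve(kin, config.classes[cls_name])

    s0 = config.baseline_signal
    signal = s0 * (1.0 + enh / 100.0) + config.noise_sd * s0 / 100.0 * unit_noise
    series = DynamicSeries(
        signal=signal,
        frame_times_s=times,
        voxel_spacing_mm=config.voxel_spacing_mm,
        n_baseline_frames=config.n_baseline_frames,
    )

    gleason = _assign_gleason(zone, kin_cancer, config.classes[cancer_label])
    specs = [
        RoiSpec(patient_id=patient_id, label=cancer_label, center=center_cancer,
                diameter_mm=d, gleason=gleason)
        for d in config.roi_diameters_mm
    ] + [
        RoiSpec(patient_id=patient_id, label=benign_label, center=center_benign, diameter_mm=d)
        for d in config.roi_diameters_mm
    ]
    truth = {
        "patient_id": patient_id,
        "zone": zone,
        "regions": [
            {"label": cancer_label, "amplitude": kin_cancer[0], "rate": kin_cancer[1],
             "delay_slope": kin_cancer[2], "gleason": gleason},
            {"label": benign_label, "amplitude": kin_benign[0], "rate": kin_benign[1],
             "delay_slope": kin_benign[2], "gleason": None},
        ],
    }
    return PatientPhantom(patient_id=patient_id, zone=zone, series=series,
                          roi_specs=specs, ground_truth=truth)


def _assign_gleason(zone: str, kin: tuple[float, float, float],
                    cls: TissueClassKinetics) -> int:
    """Grade the simulated lesion from its sampled kinetics.

    TZ: thresholding the sampled delay slope (more washout-like, i.e.
    smaller d, reads as more aggressive) -> Gleason 7 vs 6. PZ: grading by
    wash-in amplitude -> Gleason 7/8/9. This ties grade to kinetics so a
    nonzero Spearman signal exists for the correlation analysis.
    """
    a, _, d = kin
    if zone == "TZ":
        return 7 if d < cls.delay_slope_mean else 6
    if a <= cls.amplitude_mean + 0.5 * cls.amplitude_sd:
        return 7
    if a <= cls.amplitude_mean + 1.5 * cls.amplitude_sd:
        return 8
    return 9


def generate_cohort(config: PhantomConfig) -> list[PatientPhantom]:
    """Generate the full paired cohort: TZ patients first, then PZ.

    Per-patient RNG streams are spawned from the master seed, so the
    cohort is reproducible and individual patients are independent.
    """
    n_total = config.n_tz_patients + config.n_pz_patients
    streams = np.random.SeedSequence(config.seed).spawn(n_total)
    cohort: list[PatientPhantom] = []
    for i in range(n_total):
        zone = "TZ" if i < config.n_tz_patients else "PZ"
        rng = np.random.default_rng(streams[i])
        cohort.append(
            generate_phantom(config, patient_id=f"P{i + 1:02d}", zone=zone, rng=rng)
        )
    return cohort


def write_cohort(cohort: list[PatientPhantom], out_dir: str | Path) -> None:
    """Write per-patient 4D NIfTI files plus roi_specs.csv and
    ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs: list[RoiSpec] = []
    truths = []
    for patient in cohort:
        write_dynamic_series(patient.series, out / f"{patient.patient_id}.nii.gz")
        specs.extend(patient.roi_specs)
        truths.append(patient.ground_truth)
    write_roi_specs(specs, out / "roi_specs.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=2, sort_keys=True)
        fh.write("\n")
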