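"""Reading and writing of on-disk artifacts.

Covers the 4D dynamic NIfTI series, ROI specification tables, per-ROI
feature tables (including ingest of an externally produced raw histogram
spreadsheet), and the JSON statistics report.

Conventions
-----------
* Array axes are ``(slice, row, col, frame)``; voxel indices are 0-based.
* Feature tables serialize floats at 17 significant digits so that a
  write/read round trip is lossless; missing values (e.g. an undefined
  coefficient of variation) are written as empty cells, never as sentinel
  numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DimensionalityError,
    DuplicateKeyError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Tissue-class labels: cancer/normal in the transitional/peripheral zone.
LABELS = ("CTZ", "NTZ", "CPZ", "NPZ")
CANCER_LABELS = ("CTZ", "CPZ")
BENIGN_LABELS = ("NTZ", "NPZ")
#: Zone -> (cancer label, benign label)
ZONE_LABELS = {"TZ": ("CTZ", "NTZ"), "PZ": ("CPZ", "NPZ")}
MAP_NAMES = ("MWS", "DPS")

#: Canonical order of the 14 first-order histogram parameters.
FEATURE_NAMES = (
    "mean",
    "sd",
    "cv",
    "kurtosis",
    "skewness",
    "iqr",
    "p10",
    "p25",
    "p50",
    "p75",
    "p90",
    "mfwhm",
    "p90p10",
    "range",
)

#: Column order of features.csv.
FEATURE_TABLE_COLUMNS = ("patient_id", "label", "diameter_mm", "map") + FEATURE_NAMES

ROI_SPEC_COLUMNS = ("patient_id", "label", "slice", "row", "col", "diameter_mm", "gleason")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DynamicSeries:
    """A 4D dynamic contrast-enhanced series.

    Parameters
    ----------
    signal
        4D array indexed ``(slice, row, col, frame)``; arbitrary scanner
        units, non-negative.
    frame_times_s
        Acquisition time of each frame in seconds, strictly increasing.
    voxel_spacing_mm
        ``(slice, row, col)`` voxel spacing in millimetres.
    n_baseline_frames
        Number of pre-contrast frames. The acquisition protocol injects
        contrast at the beginning of the fourth measurement, so the default
        is 3.
    """

    signal: np.ndarray
    frame_times_s: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    n_baseline_frames: int = 3

    def __post_init__(self) -> None:
        signal = np.asarray(self.signal, dtype=float)
        times = np.asarray(self.frame_times_s, dtype=float)
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "frame_times_s", times)
        object.__setattr__(self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm))
        if signal.ndim != 4:
            raise DimensionalityError(f"signal must be 4D, got {signal.ndim}D")
        if times.ndim != 1 or times.size != signal.shape[3]:
            raise ValidationError(
                f"frame_times_s has length {times.size}, expected {signal.shape[3]}"
            )
        if not np.all(np.diff(times) > 0):
            raise ValidationError("frame_times_s must be strictly increasing")
        if not (2 <= self.n_baseline_frames < signal.shape[3]):
            raise ValidationError(
                "n_baseline_frames must be >= 2 and < number of frames, "
                f"got {self.n_baseline_frames} with {signal.shape[3]} frames"
            )
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValidationError(f"voxel_spacing_mm must be > 0, got {self.voxel_spacing_mm}")

    @property
    def n_frames(self) -> int:
        return int(self.signal.shape[3])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.signal.shape[:3])  # type: ignore[return-value]


@dataclass(frozen=True)
class RoiSpec:
    """Circular in-plane ROI of fixed physical diameter.

    ``center`` is a 0-based ``(slice, row, col)`` voxel index. ``gleason``
    (sum of the two pattern grades, 6-10) is only meaningful for cancer
    labels.
    """

    patient_id: str
    label: str
    center: tuple[int, int, int]
    diameter_mm: float
    gleason: int | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"unknown ROI label {self.label!r}; expected one of {LABELS}")
        if not self.diameter_mm > 0:
            raise ValidationError(f"diameter_mm must be > 0, got {self.diameter_mm}")
        if len(self.center) != 3:
            raise ValidationError("center must be a (slice, row, col) triple")
        object.__setattr__(self, "center", tuple(int(c) for c in self.center))
        if self.gleason is not None:
            if self.label not in CANCER_LABELS:
                raise ValidationError(
                    f"gleason score given for benign label {self.label!r} "
                    f"(patient {self.patient_id})"
                )
            if not 6 <= int(self.gleason) <= 10:
                raise ValidationError(f"gleason must be in 6..10, got {self.gleason}")
            object.__setattr__(self, "gleason", int(self.gleason))

    @property
    def zone(self) -> str:
        return "TZ" if self.label in ("CTZ", "NTZ") else "PZ"

    @property
    def is_cancer(self) -> bool:
        return self.label in CANCER_LABELS


@dataclass(frozen=True)
class FeatureRecord:
    """The 14 histogram parameters of one ROI on one parametric map."""

    patient_id: str
    label: str
    diameter_mm: float
    map_name: str
    features: Mapping[str, float]
    gleason: int | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")
        if self.map_name not in MAP_NAMES:
            raise ValidationError(f"map must be one of {MAP_NAMES}, got {self.map_name!r}")
        feats = dict(self.features)
        missing = set(FEATURE_NAMES) - set(feats)
        extra = set(feats) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValidationError(
                f"feature record must carry exactly the canonical parameters; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        object.__setattr__(self, "features", {k: float(feats[k]) for k in FEATURE_NAMES})

    @property
    def key(self) -> tuple[str, str, float, str]:
        return (self.patient_id, self.label, float(self.diameter_mm), self.map_name)

    @property
    def zone(self) -> str:
        return "TZ" if self.label in ("CTZ", "NTZ") else "PZ"


# ---------------------------------------------------------------------------
# 4D NIfTI series
# ---------------------------------------------------------------------------


def read_dynamic_series(
    path: str | Path,
    n_baseline_frames: int = 3,
    frame_interval_s: float | None = None,
) -> DynamicSeries:
    """Load a 4D NIfTI dynamic series.

    Voxel spacing is taken from the header. Frame times are synthesized as
    ``k * frame_interval_s``; when ``frame_interval_s`` is None the 4th
    header zoom (time step) is used, and a missing/zero time step raises
    :class:`ConfigurationError`.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise DimensionalityError(f"{path}: expected a 4D image, got {img.ndim}D")
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
    if frame_interval_s is None:
        dt = float(zooms[3]) if len(zooms) > 3 else 0.0
        if dt <= 0:
            raise ConfigurationError(
                f"{path}: no temporal metadata in header; pass frame_interval_s"
            )
        frame_interval_s = dt
    times = np.arange(data.shape[3], dtype=float) * float(frame_interval_s)
    return DynamicSeries(
        signal=data,
        frame_times_s=times,
        voxel_spacing_mm=spacing,
        n_baseline_frames=n_baseline_frames,
    )


def write_dynamic_series(series: DynamicSeries, path: str | Path) -> None:
    """Write a series as 4D NIfTI; spacing and frame interval go in the header."""
    affine = np.diag(list(series.voxel_spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(series.signal, dtype=np.float64), affine)
    intervals = np.diff(series.frame_times_s)
    img.header.set_zooms(series.voxel_spacing_mm + (float(intervals[0]),))
    img.to_filename(str(path))


def write_map(map3d: np.ndarray, voxel_spacing_mm: Sequence[float], path: str | Path) -> None:
    """Export a 3D parametric map (MWS or DPS) as NIfTI on the input grid."""
    arr = np.asarray(map3d, dtype=np.float64)
    if arr.ndim != 3:
        raise DimensionalityError(f"parametric map must be 3D, got {arr.ndim}D")
    affine = np.diag(list(voxel_spacing_mm) + [1.0])
    nib.Nifti1Image(arr, affine).to_filename(str(path))


# ---------------------------------------------------------------------------
# ROI specification tables
# ---------------------------------------------------------------------------


def read_roi_specs(path: str | Path) -> list[RoiSpec]:
    """Read a roi_specs.csv table (columns: patient_id,label,slice,row,col,
    diameter_mm,gleason; gleason optional; ``#`` comments allowed)."""
    try:
        df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty ROI specification file", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path}: ROI specification file has no rows", stacklevel=2)
        return []
    required = {"patient_id", "label", "slice", "row", "col", "diameter_mm"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing columns {sorted(missing)}; found {list(df.columns)}"
        )
    specs: list[RoiSpec] = []
    for idx, row in df.iterrows():
        gleason = None
        if "gleason" in df.columns and not pd.isna(row["gleason"]):
            gleason = int(row["gleason"])
        try:
            specs.append(
                RoiSpec(
                    patient_id=str(row["patient_id"]),
                    label=str(row["label"]),
                    center=(int(row["slice"]), int(row["row"]), int(row["col"])),
                    diameter_mm=float(row["diameter_mm"]),
                    gleason=gleason,
                )
            )
        except (ValidationError, ValueError) as err:
            raise ValidationError(f"{path} row {idx}: {err}") from err
    return specs


def write_roi_specs(specs: Iterable[RoiSpec], path: str | Path) -> None:
    rows = []
    for s in specs:
        rows.append(
            {
                "patient_id": s.patient_id,
                "label": s.label,
                "slice": s.center[0],
                "row": s.center[1],
                "col": s.center[2],
                "diameter_mm": s.diameter_mm,
                "gleason": s.gleason,
            }
        )
    df = pd.DataFrame(rows, columns=list(ROI_SPEC_COLUMNS))
    with open(path, "w") as fh:
        fh.write("# dcehist ROI specifications; voxel indices are 0-based (slice,row,col)\n")
        df.to_csv(fh, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def records_to_frame(records: Iterable[FeatureRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame in canonical column order."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "label": r.label,
            "diameter_mm": float(r.diameter_mm),
            "map": r.map_name,
        }
        row.update(r.features)
        if r.gleason is not None:
            row["gleason"] = r.gleason
        rows.append(row)
    cols = list(FEATURE_TABLE_COLUMNS)
    if any("gleason" in row for row in rows):
        cols.append("gleason")
    return pd.DataFrame(rows, columns=cols)


def write_feature_table(records: Iterable[FeatureRecord], path: str | Path) -> None:
    """Write features.csv; NaN values serialize as empty cells."""
    df = records_to_frame(records)
    if df.empty:
        df = pd.DataFrame(columns=list(FEATURE_TABLE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")


def _check_duplicate_keys(keys: Sequence[tuple]) -> None:
    seen: set[tuple] = set()
    for k in keys:
        if k in seen:
            raise DuplicateKeyError(
                f"duplicate (patient, label, diameter, map) key: {k}"
            )
        seen.add(k)


def read_feature_table(path: str | Path) -> list[FeatureRecord]:
    """Read a features.csv written by :func:`write_feature_table`."""
    return read_raw_feature_table(path)


def read_raw_feature_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sheet: str | int = 0,
) -> list[FeatureRecord]:
    """Ingest a per-ROI histogram parameter table (CSV or XLSX).

    ``column_map`` adapts foreign layouts: keys are the canonical column
    names (``patient_id``, ``label``, ``diameter_mm``, ``map``, and the 14
    parameter names), values are the column names found in the file. An
    identity mapping is assumed for unmapped columns.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        try:
            # round_trip parser: 17-significant-digit cells reparse exactly
            df = pd.read_csv(path, comment="#", float_precision="round_trip")
        except pd.errors.EmptyDataError as err:
            raise SchemaError(f"{path}: empty table") from err
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in df.columns}
        df = df.rename(columns=rename)
    required = ["patient_id", "label", "diameter_mm", "map", *FEATURE_NAMES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    records: list[FeatureRecord] = []
    for idx, row in df.iterrows():
        gleason = None
        if "gleason" in df.columns and not pd.isna(row["gleason"]):
            gleason = int(row["gleason"])
        feats = {name: float(row[name]) if not pd.isna(row[name]) else math.nan
                 for name in FEATURE_NAMES}
        try:
            records.append(
                FeatureRecord(
                    patient_id=str(row["patient_id"]),
                    label=str(row["label"]),
                    diameter_mm=float(row["diameter_mm"]),
                    map_name=str(row["map"]),
                    features=feats,
                    gleason=gleason,
                )
            )
        except (ValidationError, ValueError) as err:
            raise ValidationError(f"{path} row {idx}: {err}") from err
    _check_duplicate_keys([r.key for r in records])
    return records


# ---------------------------------------------------------------------------
# Statistics report
# ---------------------------------------------------------------------------


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _nan_to_none(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_nan_to_none(v) for v in obj]
    return obj


def write_stats_report(report: Mapping, path: str | Path) -> None:
    """Write the statistics report as JSON (NaN -> null, sorted keys)."""
    serializable = json.loads(json.dumps(report, default=_json_default))
    with open(path, "w") as fh:
        json.dump(_nan_to_none(serializable), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_stats_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
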