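"""Circular ROI geometry and per-voxel value extraction.

ROIs are strictly in-plane circles of fixed physical diameter (protocol
values 7.5 and 10 mm), so results are comparable across ROIs regardless of
pixel size. A voxel belongs to the mask when its center lies within the
circle (center-in-circle rule); anisotropic pixel spacing is honoured by
measuring distance in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyRoiError, RoiCoverageError, RoiOutOfBoundsError, ValidationError
from .io import RoiSpec
from .kinetics import SlopeMaps


@dataclass(frozen=True)
class RoiSample:
    """Per-voxel map values extracted from one ROI.

    ``values`` contains only the non-missing voxels; ``n_missing`` counts
    the mask voxels that were NaN on the map.
    """

    spec: RoiSpec
    map_name: str
    values: np.ndarray
    n_voxels: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.n_voxels != values.size or values.size < 1:
            raise ValidationError("n_voxels must equal len(values) >= 1")


def circular_mask(
    center: tuple[int, int],
    diameter_mm: float,
    pixel_spacing_mm: tuple[float, float],
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """In-plane voxel indices of a circle of physical diameter.

    Returns an ``(n, 2)`` int array of ``(row, col)`` indices whose voxel
    centers lie within Euclidean physical distance ``diameter_mm / 2`` of
    the center voxel's center. When ``shape`` is given, a mask reaching
    outside the image raises :class:`RoiOutOfBoundsError` (the protocol
    requires the ROI to sit inside the lesion, hence inside the image).
    """
    if diameter_mm <= 0:
        raise ValidationError(f"diameter_mm must be > 0, got {diameter_mm}")
    sr, sc = (float(s) for s in pixel_spacing_mm)
    if sr <= 0 or sc <= 0:
        raise ValidationError(f"pixel spacing must be > 0, got {pixel_spacing_mm}")
    r0, c0 = (int(c) for c in center)
    radius = diameter_mm / 2.0
    # bounding box in voxel units, then exact distance test on voxel centers
    nr = int(np.floor(radius / sr))
    nc = int(np.floor(radius / sc))
    rr, cc = np.meshgrid(
        np.arange(r0 - nr, r0 + nr + 1), np.arange(c0 - nc, c0 + nc + 1), indexing="ij"
    )
    dist2 = ((rr - r0) * sr) ** 2 + ((cc - c0) * sc) ** 2
    inside = dist2 <= radius**2
    idx = np.column_stack([rr[inside], cc[inside]]).astype(int)
    if shape is not None:
        if (
            idx[:, 0].min() < 0
            or idx[:, 1].min() < 0
            or idx[:, 0].max() >= shape[0]
            or idx[:, 1].max() >= shape[1]
        ):
            raise RoiOutOfBoundsError(
                f"circular ROI at {center} with diameter {diameter_mm} mm "
                f"extends beyond the {shape} image plane"
            )
    return idx


def extract_roi(
    maps: SlopeMaps,
    spec: RoiSpec,
    map_name: str,
    voxel_spacing_mm: tuple[float, float, float],
    missing_cap: float = 0.10,
) -> RoiSample:
    """Extract per-voxel map values inside a circular ROI.

    Missing (NaN) voxels are dropped and counted; an ROI that is entirely
    missing raises :class:`EmptyRoiError`, and a missing fraction above
    ``missing_cap`` raises :class:`RoiCoverageError`.
    """
    if map_name not in ("MWS", "DPS"):
        raise ValidationError(f"map_name must be MWS or DPS, got {map_name!r}")
    map3d = maps.mws if map_name == "MWS" else maps.dps
    sl, row, col = spec.center
    if not 0 <= sl < map3d.shape[0]:
        raise RoiOutOfBoundsError(f"ROI slice {sl} outside image with {map3d.shape[0]} slices")
    idx = circular_mask(
        (row, col), spec.diameter_mm, (voxel_spacing_mm[1], voxel_spacing_mm[2]),
        shape=map3d.shape[1:],
    )
    raw = map3d[sl, idx[:, 0], idx[:, 1]]
    missing = np.isnan(raw)
    n_missing = int(missing.sum())
    if n_missing == raw.size:
        raise EmptyRoiError(
            f"all {raw.size} voxels missing in ROI {spec.patient_id}/{spec.label} on {map_name}"
        )
    if n_missing / raw.size > missing_cap:
        raise RoiCoverageError(
            f"{n_missing}/{raw.size} voxels missing in ROI "
            f"{spec.patient_id}/{spec.label} on {map_name} (cap {missing_cap:.0%})"
        )
    values = raw[~missing]
    return RoiSample(
        spec=spec, map_name=map_name, values=values, n_voxels=values.size, n_missing=n_missing
    )
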