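"""Exception hierarchy.

Every error raised by this package derives from :class:`DceHistError`, so
callers (and the CLI) can map failures to a machine-readable error class.
"""


class DceHistError(Exception):
    """Base class for all dcehist errors."""


class DimensionalityError(DceHistError):
    """Image does not have the expected number of dimensions."""


class ConfigurationError(DceHistError):
    """Missing or inconsistent configuration (e.g. no temporal metadata)."""


class ValidationError(DceHistError):
    """A record or value violates the package's domain contracts."""


class SchemaError(DceHistError):
    """A tabular input lacks required columns."""


class DuplicateKeyError(DceHistError):
    """Two records share a (patient, label, diameter, map) key."""


class NoInflowError(DceHistError):
    """No frame of the series crosses the contrast-arrival threshold."""


class InvalidVoxelError(DceHistError):
    """A voxel time course cannot be normalized (non-positive baseline)."""


class RoiOutOfBoundsError(DceHistError):
    """A circular ROI mask extends beyond the image grid."""


class EmptyRoiError(DceHistError):
    """Every voxel inside an ROI is missing on the requested map."""


class RoiCoverageError(DceHistError):
    """Too large a fraction of ROI voxels is missing on the requested map."""


class InsufficientSampleError(DceHistError):
    """Fewer values than the minimum required for histogram analysis."""


class LayoutError(DceHistError):
    """Synthetic phantom regions overlap or fall outside the grid."""
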