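"""Exception hierarchy shared across the package."""


class DwidistortError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(DwidistortError, ValueError):
    """A volume file could not be read in the supported format."""


class LabelError(DwidistortError, ValueError):
    """Voxel data are not valid organ labels."""


class SchemaError(DwidistortError, ValueError):
    """A delimited-text table does not match the documented schema."""


class ValidationError(DwidistortError, ValueError):
    """Record-level validation failure (e.g. an out-of-scale score)."""


class BoundsError(DwidistortError, ValueError):
    """Geometry falls outside the target voxel grid."""


class DegenerateInputError(DwidistortError, ValueError):
    """An input is structurally valid but degenerate (empty mask, zero-area polygon)."""


class EmptyPairingError(DwidistortError, ValueError):
    """No slices could be paired between the two contour sets."""


class ContractError(DwidistortError, ValueError):
    """Two intermediate results that must share a convention do not."""
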