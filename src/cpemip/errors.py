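"""Exception hierarchy used across the pipeline."""


class CpeMipError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CpeMipError):
    """Input file or array is not in the expected format."""


class GeometryError(CpeMipError):
    """Grids that must share a voxel lattice do not."""


class ValidationError(CpeMipError):
    """Semantically invalid input (labels, manifests, empty sets...)."""


class SegmentationError(CpeMipError):
    """Lung segmentation failed or produced an unusable mask."""


class ConfigError(CpeMipError):
    """Invalid configuration value."""
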