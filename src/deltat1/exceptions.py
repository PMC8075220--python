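"""Exception hierarchy shared across the package."""


class DeltaT1Error(Exception):
    """Base class for all package-specific errors."""


class DomainError(DeltaT1Error, ValueError):
    """A physical quantity is outside its meaningful domain (e.g. T1 <= 0)."""


class ConfigurationError(DeltaT1Error, ValueError):
    """A protocol, phantom, or run configuration is internally inconsistent."""


class GeometryError(DeltaT1Error, ValueError):
    """Volumes do not share a grid (shape and affine) where they must."""


class UnitError(DeltaT1Error, ValueError):
    """Operands carry incompatible unit tags."""


class EmptyRoiError(DeltaT1Error, ValueError):
    """An ROI is empty after missing-value exclusion."""


class PlacementError(DeltaT1Error, RuntimeError):
    """Lesions could not be placed without overlap within the retry budget."""


class DegenerateInputError(DeltaT1Error, ValueError):
    """Input is too degenerate for the requested computation."""


class FormatError(DeltaT1Error, IOError):
    """A file could not be parsed as the expected on-disk format."""
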