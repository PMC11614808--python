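"""Exception hierarchy shared across retinaquant modules."""


class RetinaQuantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RetinaQuantError, ValueError):
    """Invalid configuration object (bad field values, missing reference gene, ...)."""


class ParameterError(RetinaQuantError, ValueError):
    """Invalid operation parameter (negative sigma, even block size, ...)."""


class FormatError(RetinaQuantError, ValueError):
    """Unreadable or inconsistent file content (plane/channel mismatch, ...)."""


class RoiKindError(RetinaQuantError, TypeError):
    """Operation applied to the wrong ROI kind (polyline where polygon expected)."""


class DimensionError(RetinaQuantError, ValueError):
    """Array shape mismatch between operands."""


class DegenerateInputError(RetinaQuantError, ValueError):
    """Input carries no usable signal (constant plane, too few distinct values)."""


class CapacityError(RetinaQuantError, RuntimeError):
    """Scene placement failed: too many cells for the separation constraint."""
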