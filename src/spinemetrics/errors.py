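"""Exception hierarchy shared by all spinemetrics modules."""


class SpinemetricsError(Exception):
    """Base class for all package-specific errors."""


class SchemaViolationError(SpinemetricsError, ValueError):
    """A label image contains values outside the six-class schema."""


class GeometryError(SpinemetricsError, ValueError):
    """A phantom specification describes mutually inconsistent anatomy."""


class AnatomyNotFoundError(SpinemetricsError, RuntimeError):
    """A required anatomical structure could not be located."""


class RegionAbsentError(AnatomyNotFoundError):
    """A required region (IVD or PE) has no pixels in the label image."""


class EmptyBoundaryError(AnatomyNotFoundError):
    """A region exists but has no important-boundary pixels."""


class ForamenNotFoundError(AnatomyNotFoundError):
    """No candidate boundary points on the requested foraminal side."""


class CanalNotFoundError(AnatomyNotFoundError):
    """No posterior-element boundary point between B_L and B_R."""
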