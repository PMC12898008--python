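"""Exception types shared across the package."""


class OsteomarginError(Exception):
    """Base class for package errors."""


class EmptyForegroundError(OsteomarginError):
    """An operation requiring a nonempty foreground received an empty mask."""


class GridMismatchError(OsteomarginError):
    """Two volumes that must share geometry (grid or world extent) do not."""


class PadTooSmallError(OsteomarginError):
    """The ROI padding cannot accommodate the requested safety margin."""


class DegenerateGeometryError(OsteomarginError):
    """Point set too small or degenerate (coplanar) for surface reconstruction."""
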