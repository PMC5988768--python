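"""Exception hierarchy shared across the package."""


class PSOCTError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(PSOCTError, ValueError):
    """Tissue or acquisition geometry is unphysical (non-positive sizes, bad grids)."""


class DomainError(PSOCTError, ValueError):
    """A scalar argument lies outside its mathematical domain."""


class RangeError(PSOCTError, IndexError):
    """A position or index falls outside the image / tissue block."""


class ShapeMismatchError(PSOCTError, ValueError):
    """Co-registered arrays disagree in shape."""


class NoSurfaceError(PSOCTError):
    """No pixel in an intensity column exceeds the surface threshold."""


class InsufficientDepthError(PSOCTError):
    """Signal falls below the depth threshold immediately below the surface."""


class DegenerateProfileError(PSOCTError, ValueError):
    """A profile is too short for the requested operation."""


class InsufficientDataError(PSOCTError, ValueError):
    """A statistical group has too few values."""


class PipelineError(PSOCTError):
    """Wraps a stage failure with the B-scan index it occurred in."""

    def __init__(self, bscan_index: int, stage: str, cause: Exception):
        self.bscan_index = bscan_index
        self.stage = stage
        self.cause = cause
        super().__init__(f"B-scan {bscan_index}, stage '{stage}': {cause!r}")
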