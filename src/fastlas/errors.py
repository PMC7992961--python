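"""Exception hierarchy for fastlas."""


class FastlasError(Exception):
    """Base class for all fastlas errors."""


class FormatError(FastlasError):
    """Malformed or inconsistent input file (mixed shapes, missing header fields)."""


class InvariantError(FastlasError):
    """A domain-type invariant was violated (bad frame count, out-of-bounds point, ...)."""


class ZeroVarianceError(FastlasError):
    """A flat intensity patch makes normalized cross-correlation undefined."""


class TrackingBoundsError(FastlasError):
    """The search window left the image; names the frame and point."""

    def __init__(self, frame: int, point: str, message: str | None = None):
        self.frame = frame
        self.point = point
        super().__init__(
            message or f"search window out of image bounds at frame {frame}, point {point!r}"
        )


class GeometryError(FastlasError):
    """Phantom geometry leaves the image at peak strain, or degenerate geometry."""


class StatsError(FastlasError):
    """Invalid input to a cohort-statistics routine."""


class ConvergenceError(StatsError):
    """A model fit failed to converge (e.g. complete separation in Cox regression)."""
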