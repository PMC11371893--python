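"""Exception hierarchy.

Every error raised by the package derives from :class:`CoroQCAError`, so
callers can catch one type at a pipeline boundary.  Errors raised while
processing a particular vessel carry ``vessel_id`` where it is known.
"""


class CoroQCAError(Exception):
    """Base class for all package errors."""

    def __init__(self, message: str, vessel_id: str | None = None):
        self.vessel_id = vessel_id
        if vessel_id is not None:
            message = f"[vessel {vessel_id}] {message}"
        super().__init__(message)


class InvalidGeometryError(CoroQCAError):
    """Centerline, polygon, or area profile violates a geometric precondition."""


class ParameterError(CoroQCAError):
    """A function argument is outside its admissible range."""


class DegenerateVesselError(CoroQCAError):
    """Reference-line fit failed: too few healthy samples to define a reference."""


class OstialLesionError(CoroQCAError):
    """Lesion runs off an end of the vessel; no reference crossing on that side.

    Mirrors the exclusion of ostial/truncated lesions from the analysis.
    """


class InvalidSegmentError(CoroQCAError):
    """A lesion segment violates its invariants (ordering, positivity)."""


class AlignmentError(CoroQCAError):
    """Two per-vessel profiles do not share a compatible arc-length range/grid."""


class ConfigError(CoroQCAError):
    """A configuration object failed validation."""


class SchemaError(CoroQCAError):
    """An input file violates the documented schema (names file/row/column)."""


class AnalysisError(CoroQCAError):
    """A statistical stage cannot run on the supplied cohort."""
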