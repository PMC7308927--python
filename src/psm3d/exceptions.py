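"""Exception hierarchy for psm3d."""


class PSMError(Exception):
    """Base class for all psm3d errors."""


class InvalidPlaneError(PSMError):
    """A plane with a zero normal (or otherwise unusable coefficients)."""


class DegenerateInputError(PSMError):
    """Collinear / coincident points where a unique plane is required."""


class NoUniqueLineError(PSMError):
    """Two parallel or identical planes do not intersect in a unique line."""


class InsufficientDataError(PSMError):
    """Fewer points than the operation needs."""


class AmbiguousPeakError(PSMError):
    """Accumulator peak is not unique in a structural sense (e.g. all
    points coincident, so every (theta, phi) column peaks equally)."""


class ConfigError(PSMError):
    """Invalid run / simulation / database configuration."""


class GeometryError(PSMError):
    """Geometric preconditions violated (e.g. contact point off-plane)."""


class NoMatchError(PSMError):
    """No sector of the database matches the probe plane.

    Carries the standard advice of the matching procedure: rebuild the
    sector database with a larger vertical resolution.
    """

    def __init__(self, message: str = "no sector matched the probe plane; "
                 "rebuild the sector database with a larger vertical "
                 "resolution (delta_v)"):
        super().__init__(message)
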