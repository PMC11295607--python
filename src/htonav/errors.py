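"""Exception hierarchy for htonav.

``DegenerateGeometryError`` signals numerically ill-posed input (collinear
landmark sets, zero-length normals, degenerate plane projections); the CLI maps
it to exit code 2.  All other validation failures raise standard ``ValueError``
subclasses and map to exit code 1.
"""


class HtonavError(Exception):
    """Base class for package-specific errors."""


class DegenerateGeometryError(HtonavError):
    """Input geometry is numerically degenerate (collinear points, zero normal,
    projection of a normal onto a coordinate plane vanishing, ...)."""


class MeshParseError(HtonavError, ValueError):
    """A mesh file could not be parsed; the message names the file and, where
    the underlying parser reports it, the offending location."""


class LandmarkFileError(HtonavError, ValueError):
    """A landmark CSV violates the required dialect (columns, duplicate labels,
    non-numeric coordinates)."""


class LandmarkMatchError(HtonavError, ValueError):
    """Landmark sets cannot be paired: too few / too many shared labels.
    Carries the offending label lists in the message."""
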