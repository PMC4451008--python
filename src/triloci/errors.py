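"""Exception types shared across the package."""


class TriplocError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TriplocError, ValueError):
    """A coordinate table violates the expected layout or content."""


class DegenerateGeometryError(TriplocError, ValueError):
    """Two or more spots of a nucleus coincide, so the triangle is undefined."""


class DegenerateInputError(TriplocError, ValueError):
    """A statistical input is degenerate (e.g. a zero-variance column)."""
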