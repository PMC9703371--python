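"""Exception types shared across the pipeline.

Validation failures (bad geometry, missing control points, shape
mismatches) are distinguished from I/O failures so the command-line
layer can map them to distinct exit codes.
"""


class GelSpotError(Exception):
    """Base class for all gelspot errors."""


class ValidationError(GelSpotError):
    """Input violates a documented precondition or invariant."""


class DegenerateGeometryError(ValidationError):
    """Control points are coincident or otherwise unusable."""
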