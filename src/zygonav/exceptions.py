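"""Exception hierarchy.

Validation failures map to CLI exit code 2, non-convergence to 3.
"""


class ZygonavError(Exception):
    """Base class for all package errors."""


class ValidationError(ZygonavError):
    """Invalid input data: malformed files, non-rigid matrices, bad shapes."""


class MeshFormatError(ValidationError):
    """Unreadable or structurally invalid mesh file."""


class DegenerateGeometryError(ValidationError):
    """Geometrically degenerate configuration (collinear landmarks, empty region)."""


class PlanStateError(ValidationError):
    """Operation attempted in an invalid plan state (e.g. marks after reduction)."""


class ConvergenceError(ZygonavError):
    """Iterative registration failed to converge or found no correspondences."""
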