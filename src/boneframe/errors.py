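"""Exception and warning hierarchy.

Errors are split into input errors (bad files, bad parameters; CLI exit
code 2) and computational errors (an algorithm could not produce a valid
result; CLI exit code 1).
"""


class BoneframeError(Exception):
    """Base class for all package errors."""


class InputError(BoneframeError):
    """Unusable input: missing/corrupt file or invalid parameter value."""


class MeshLoadError(InputError):
    """A mesh file could not be read or parsed."""


class MeshValidationError(BoneframeError):
    """A mesh violates a structural requirement (e.g. not watertight)."""


class DegenerateFrameError(BoneframeError):
    """A body coordinate frame could not be constructed."""


class GrooveNotFoundError(BoneframeError):
    """Fewer than two concave groove arcs were detected in a section."""


class EmptySectionError(BoneframeError):
    """A cutting plane does not intersect the mesh."""


class CollinearPointsError(BoneframeError):
    """Circle fitting was attempted on (near-)collinear points."""


class DegeneracyWarning(UserWarning):
    """Raised when a deterministic fallback replaces an ill-defined choice
    (degenerate principal moments, exact ties in a scan, ...)."""
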