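"""Exception hierarchy."""


class AneumorphError(Exception):
    """Base class for package errors."""


class FormatError(AneumorphError):
    """A file could not be parsed, or violates a format contract."""


class ValidationError(AneumorphError):
    """Input data violates a documented invariant."""


class ResolutionError(AneumorphError):
    """Voxel spacing too coarse to resolve the requested structure."""


class EmptyMaskError(AneumorphError):
    """A binary volume contains no foreground, so no surface exists."""


class DisconnectedMeshError(AneumorphError):
    """The mesh edge graph is not connected where connectivity is required."""


class NonManifoldMeshError(AneumorphError):
    """An edge is shared by more than two faces."""


class NonSeparatingCurveError(AneumorphError):
    """Removing the neck curve leaves the mesh in a single component."""


class DegenerateStatisticError(AneumorphError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
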