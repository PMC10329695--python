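"""Exception hierarchy."""


class LittplanError(Exception):
    """Base class for all littplan errors."""


class GeometryError(LittplanError):
    """A phantom geometry constraint is violated (tumor outside the domain,
    fiber outside the domain, probe outside the domain, ...)."""


class ResolutionError(LittplanError):
    """The requested discretization cannot represent the requested feature
    (e.g. voxel spacing coarser than the safety-margin thickness)."""


class UnsupportedModeError(LittplanError):
    """A feature was requested in a phantom mode that does not support it
    (e.g. vessels in the homogeneous axisymmetric mode)."""


class ConfigError(LittplanError):
    """A run configuration file is invalid; the message names the key."""


class SolverError(LittplanError):
    """The linear solve failed or the time integration diverged."""
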