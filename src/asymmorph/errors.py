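"""Exception hierarchy for asymmorph.

All package-specific failures derive from :class:`AsymmorphError` so callers
can catch one base class at pipeline boundaries.
"""


class AsymmorphError(Exception):
    """Base class for all asymmorph errors."""


class LandmarkFormatError(AsymmorphError, ValueError):
    """A landmark file is malformed (bad XML, missing attribute/column, bad TPS block)."""


class CongruenceError(AsymmorphError, ValueError):
    """Configurations in one study disagree in landmark count, dimension or labels."""


class SymmetryMapError(AsymmorphError, ValueError):
    """A paired/median landmark declaration is invalid for the configuration."""


class DegenerateConfigurationError(AsymmorphError, ValueError):
    """All landmarks coincide (zero centroid size) or a fit is rank-deficient."""


class ConvergenceError(AsymmorphError, RuntimeError):
    """Iterative superimposition failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DesignError(AsymmorphError, ValueError):
    """The replication/grouping structure does not support the requested analysis."""


class ConfigError(AsymmorphError, ValueError):
    """A study configuration file is inconsistent or references missing inputs."""
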