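"""Exception hierarchy shared across the package."""


class LineDriftError(Exception):
    """Base class for all package-specific errors."""


class InvalidGroupSizeError(LineDriftError, ValueError):
    """A group summary has too few individuals for the requested operation."""


class InsufficientDataError(LineDriftError, ValueError):
    """Not enough observations to compute the requested statistic."""


class DegenerateVarianceError(LineDriftError, ValueError):
    """A variance required in a denominator is zero."""


class NotTestableError(LineDriftError, ValueError):
    """A trait lacks the heritability or family count the drift test needs."""


class PedigreeError(LineDriftError, ValueError):
    """Base class for pedigree validation failures."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor."""


class DuplicateIdError(PedigreeError):
    """Two pedigree records share an id."""


class DanglingParentError(PedigreeError):
    """A parent id does not appear as an individual."""


class NoIndividualsError(PedigreeError):
    """A generation/line selection matched nobody."""


class EventLogError(LineDriftError, ValueError):
    """Malformed operant event log."""


class ConfigError(LineDriftError, ValueError):
    """Invalid simulation or pipeline configuration."""


class BreedingFailureError(LineDriftError, RuntimeError):
    """The simulated colony ran out of eligible breeding pairs."""
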