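"""Exception hierarchy shared across the package.

All errors derive from :class:`ClimNicheError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
bad scalar inputs, bad configuration, malformed data files, degenerate
statistical inputs, and mid-pipeline failures.
"""


class ClimNicheError(Exception):
    """Base class for all package errors."""


class DomainError(ClimNicheError, ValueError):
    """A scalar argument is outside the mathematical domain of an operation."""


class ConfigurationError(ClimNicheError, ValueError):
    """A configuration object or parameter set is invalid."""


class DataError(ClimNicheError, ValueError):
    """Input data are malformed or incomplete (e.g. missing months/years)."""


class DegenerateInputError(ClimNicheError, ValueError):
    """An input is formally valid but statistically degenerate (zero SD, ...)."""


class PipelineError(ClimNicheError, RuntimeError):
    """A pipeline stage cannot proceed (empty county set, missing artifact)."""


class GenerationError(ClimNicheError, RuntimeError):
    """Synthetic-data generation produced an invalid state (population <= 0)."""


class CollinearityError(ClimNicheError, RuntimeError):
    """A local weighted design is numerically rank deficient.

    Carries the location index so the caller can retry with a wider kernel.
    """

    def __init__(self, location: int, condition: float):
        self.location = location
        self.condition = condition
        super().__init__(
            f"local design at location {location} is ill-conditioned "
            f"(condition number {condition:.3g})"
        )


class BandwidthError(ClimNicheError, ValueError):
    """An adaptive bandwidth leaves too few neighbours for the local fit."""
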