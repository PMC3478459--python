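"""Exception hierarchy shared across the package.

Every error raised on a user-facing code path derives from
:class:`GeneriskError`, so callers can catch one base class at pipeline
boundaries while tests assert on the specific subclass.
"""


class GeneriskError(Exception):
    """Base class for all package-specific errors."""


class FileFormatError(GeneriskError):
    """A delimited input file violates the expected layout or value domain."""


class DuplicateIdentifierError(GeneriskError):
    """Probe or patient identifiers are not unique."""


class EmptyCohortError(GeneriskError):
    """An operation received (or produced) a cohort with no patients."""


class DegenerateGroupError(GeneriskError):
    """A comparison group is empty or otherwise uninformative."""


class NoEventsError(GeneriskError):
    """Survival input contains no observed events."""


class NoValidCutpointError(GeneriskError):
    """No admissible dichotomizing cutpoint exists (constant values or an
    empty quantile window)."""


class DomainError(GeneriskError):
    """A numeric argument lies outside its mathematical domain."""


class MissingProbeError(GeneriskError):
    """A model probe is absent from the expression matrix."""

    def __init__(self, probe_ids):
        self.probe_ids = list(probe_ids)
        super().__init__(f"probes absent from expression matrix: {self.probe_ids}")


class SeparationError(GeneriskError):
    """Monotone partial likelihood: the binary covariate perfectly separates
    events, so the Cox coefficient diverges."""


class ConstantCovariateError(GeneriskError):
    """A covariate is constant across patients and cannot be fitted."""


class ConvergenceError(GeneriskError):
    """An iterative fit exhausted its iteration budget."""


class ConfigError(GeneriskError):
    """A simulation or pipeline configuration is invalid."""
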