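"""Exception hierarchy shared by the pipeline stages."""


class PreictalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PreictalError, ValueError):
    """A configuration value violates its invariants (bad cutoff, bad onsets, ...)."""


class DataError(PreictalError, ValueError):
    """The supplied data cannot be processed (too short, single class, ...)."""


class PatientExclusionError(DataError):
    """The patient does not meet the inclusion floor (fewer than four seizures)."""


class ConvergenceError(PreictalError, RuntimeError):
    """An iterative fit failed to converge."""
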