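"""Package-specific exceptions."""


class BiofilmCAError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(BiofilmCAError, ValueError):
    """A model or analysis parameter is outside its domain."""


class NoPopulationError(BiofilmCAError, ValueError):
    """An operation that requires occupied sites was called on an empty lattice."""


class ExtinctionError(BiofilmCAError, RuntimeError):
    """The population went extinct before reaching confluence."""


class ZeroVarianceError(BiofilmCAError, ValueError):
    """Autocorrelation is undefined: the pattern has fewer than two colors."""


class InsufficientDataError(BiofilmCAError, ValueError):
    """Not enough (or invalid) samples for the requested estimator."""


class PatternFormatError(BiofilmCAError, ValueError):
    """A pattern file is malformed (bad value or ragged rows)."""
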