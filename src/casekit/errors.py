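"""Exception hierarchy shared across the package."""


class CasekitError(Exception):
    """Base class for all casekit errors."""


class FormatError(CasekitError):
    """A file does not conform to its declared format (missing column, bad header...)."""


class ValidationError(CasekitError):
    """Well-formed input carrying an invalid value (negative count, start >= end...)."""


class DegenerateNullError(CasekitError):
    """The permutation null has zero spread; a Gaussian tail cannot be fitted."""


class UndefinedResultError(CasekitError):
    """The requested statistic is undefined for the given input (e.g. no samples)."""
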