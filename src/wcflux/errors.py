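"""Exception hierarchy used across the pipeline.

All errors derive from :class:`WcfluxError` so callers can catch the
package's failures with one clause; individual classes also subclass the
matching built-in (``ValueError``, ``KeyError``) where one exists.
"""


class WcfluxError(Exception):
    """Base class for all wcflux errors."""


class InvalidArgumentError(WcfluxError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(WcfluxError, ValueError):
    """Input is structurally valid but too degenerate to process
    (e.g. a time series with fewer than two distinct time points)."""


class InsufficientReferenceError(WcfluxError, ValueError):
    """Too few wild-type reference points to build a boundary."""


class DegenerateLabelError(WcfluxError, ValueError):
    """Training labels contain a single class; the classifier cannot be fit."""


class MissingSeriesError(WcfluxError, KeyError):
    """A simulation lacks the flux series of a required reaction."""


class UndefinedStatisticError(WcfluxError, ValueError):
    """A statistic is undefined for the given input (e.g. a zero margin
    in a 2x2 contingency table)."""


class UnclassifiedPhenotypeError(WcfluxError, ValueError):
    """A phenotype flag combination is not in the class table."""


class ParseError(WcfluxError, ValueError):
    """A tabular input file is malformed; the message names the offence
    and, where possible, the line."""


class DegenerateFitWarning(UserWarning):
    """A statistical fit was degenerate and a documented fallback value
    was returned (e.g. an all-zero abnormality-frequency vector)."""
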