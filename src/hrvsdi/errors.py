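"""Exception types shared across the pipeline."""


class HrvSdiError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(HrvSdiError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(HrvSdiError, ValueError):
    """Too few samples/peaks/points to perform the operation."""


class EmptyInputError(HrvSdiError, ValueError):
    """An input file or series is empty."""


class ParseError(HrvSdiError, ValueError):
    """A text input could not be parsed; the message names the line."""


class FormatError(HrvSdiError, ValueError):
    """Input layout is inconsistent with the declared format (e.g. sampling rate)."""


class UndefinedStatisticError(HrvSdiError, ValueError):
    """A statistic is mathematically undefined for this input (constant series, single-class labels, zero differences)."""
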