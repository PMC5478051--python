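"""Exception hierarchy.

Argument errors signal a violated precondition, format errors a malformed
input file, computation errors a quantity that cannot be computed from
otherwise valid input (e.g. zero comparable sites between two sequences).
"""


class RiverscapeError(Exception):
    """Base class for all package errors."""


class ArgumentError(RiverscapeError, ValueError):
    """A function argument violates a documented precondition."""


class FormatError(RiverscapeError, ValueError):
    """An input file or serialized object is malformed."""


class ComputationError(RiverscapeError, RuntimeError):
    """A requested quantity is undefined for the given (valid) input."""


class InputError(RiverscapeError, ValueError):
    """Inconsistent analysis inputs (e.g. id mismatches across files)."""
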