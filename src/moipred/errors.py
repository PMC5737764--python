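"""Exception hierarchy shared across the package.

``ParseError``/``ValidationError`` signal malformed or out-of-contract input
files (CLI exit code 2); ``ContractError`` signals an internal contract
violation such as a catalogue mismatch between a model and a matrix (CLI exit
code 3).
"""


class MoipredError(Exception):
    """Base class for package errors."""


class ParseError(MoipredError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(MoipredError):
    """A parsed value violates a declared invariant (e.g. AF outside [0,1])."""


class ReferenceMismatchError(MoipredError):
    """A variant's REF allele disagrees with the reference genome."""


class ContractError(MoipredError):
    """An API contract was violated (catalogue mismatch, unknown level, ...)."""
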