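"""Exception hierarchy shared by all confsel modules."""


class ConfselError(Exception):
    """Base class for all errors raised by confsel."""


class ParseError(ConfselError):
    """A file could not be parsed; the message names the offending frame/line."""


class CompositionError(ConfselError):
    """Frames of an ensemble do not share the same ordered element composition."""


class ContractError(ConfselError, ValueError):
    """A documented precondition of an operation was violated."""


class ConfigurationError(ConfselError):
    """An invalid combination of user-facing options was requested."""


class StructuralMismatchError(ConfselError):
    """Two structures are not graph-isomorphic and cannot be compared."""


class UnknownElementError(ConfselError, KeyError):
    """An element symbol is missing from the covalent-radii table."""
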