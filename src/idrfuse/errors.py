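"""Exception hierarchy shared across the package."""


class IdrFuseError(Exception):
    """Base class for all package errors."""


class FormatError(IdrFuseError):
    """A file does not follow its declared on-disk layout."""


class ContractError(IdrFuseError):
    """Inputs violate an operation's stated precondition (shapes, lengths)."""


class ParameterError(IdrFuseError):
    """A configuration value is outside its admissible range."""


class DataError(IdrFuseError):
    """A dataset is unusable for the requested operation (empty, single-class...)."""
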