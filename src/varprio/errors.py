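"""Exception hierarchy shared across the package."""


class VarprioError(Exception):
    """Base class for all package errors."""


class ParseError(VarprioError):
    """An input file could not be parsed."""


class ConfigurationError(VarprioError):
    """A table or run configuration is malformed (missing columns, bad thresholds)."""


class ValidationError(VarprioError):
    """Data violates a documented invariant (e.g. REF disagrees with the reference)."""


class ContractError(VarprioError):
    """A function precondition was violated (e.g. non-normalized variant passed in)."""


class LoadError(VarprioError):
    """A knowledge-base snapshot is internally inconsistent."""


class GenerationError(VarprioError):
    """A synthetic study design is unrealizable or generation self-checks failed."""
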