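"""Exception hierarchy shared across the pipeline stages."""


class QconvError(Exception):
    """Base class for all package errors."""


class SchemaError(QconvError):
    """An input file does not expose the columns the schema requires."""


class IntegrityError(QconvError):
    """Input violates a uniqueness or consistency invariant."""


class EmptyTermSetError(QconvError):
    """Tokenization produced no terms (query was all punctuation)."""


class DegenerateInputError(QconvError):
    """A statistic is undefined on this input (zero variance, zero entropy...)."""
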