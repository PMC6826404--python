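"""Exception hierarchy for cernet.

Every error raised on purpose by the package derives from :class:`CernetError`
so callers can catch pipeline failures without masking programming errors.
"""


class CernetError(Exception):
    """Base class for all cernet errors."""


class ParameterError(CernetError, ValueError):
    """An argument or configuration value violates a documented invariant."""


class AnnotationError(CernetError, KeyError):
    """A gene is missing required annotation (e.g. transcript length for FPKM)."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class DegenerateInputError(CernetError, ValueError):
    """Input is structurally valid but statistically degenerate.

    Examples: an all-zero library column (normalization undefined) or a
    constant expression vector (rank correlation undefined).
    """


class MissingIdError(CernetError, KeyError):
    """An identifier referenced by one table is absent from another."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class ParseError(CernetError, ValueError):
    """A text input file does not conform to its dialect."""


class SequenceError(CernetError, ValueError):
    """A nucleotide sequence contains characters outside its alphabet."""


class ValidationError(CernetError, ValueError):
    """A configuration file failed validation; message carries the key path."""
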