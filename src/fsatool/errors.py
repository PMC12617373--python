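"""Exception hierarchy shared across the package."""


class FsaError(Exception):
    """Base class for all fsatool errors."""


class EmptyInputError(FsaError):
    """An input file or alignment contained no usable records."""


class AlignmentWidthError(FsaError):
    """Sequences in an alignment do not share a common length."""


class AlphabetError(FsaError):
    """A sequence contains a character outside the amino-acid alphabet."""


class PssmFormatError(FsaError):
    """A PSSM file does not follow the expected ASCII dialect."""


class PssmParseError(PssmFormatError):
    """A PSSM file cell could not be parsed as a number."""


class UndefinedColumnError(FsaError):
    """An alignment column has no usable (non-gap, non-X) characters."""


class SchemeError(FsaError):
    """A chemical-class scheme is not a partition of the 20 amino acids."""


class ParameterError(FsaError):
    """A parameter value is outside its valid range."""


class IncompatibleInputsError(FsaError):
    """Two inputs that must agree (length, scheme) do not."""


class KeyRangeError(FsaError):
    """A key residue position falls outside the annotated sequence."""
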