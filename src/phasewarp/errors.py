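"""Exception hierarchy shared across the package."""


class PhasewarpError(Exception):
    """Base class for all errors raised by phasewarp."""


class FastaFormatError(PhasewarpError):
    """The input is not well-formed FASTA."""


class SequenceValidationError(PhasewarpError):
    """A sequence contains characters outside the accepted alphabet."""


class CoordinateError(PhasewarpError):
    """Genomic coordinates are inconsistent (e.g. end < start)."""


class EmptyInputError(PhasewarpError):
    """An operation received an empty sequence, signal or record list."""


class ParameterError(PhasewarpError):
    """A parameter is out of its valid range for the given input."""
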