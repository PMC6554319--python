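"""Exception hierarchy shared by all stages."""


class DesatsigError(Exception):
    """Base class for all package errors."""


class FastaParseError(DesatsigError):
    """Malformed FASTA input (bad header, empty sequence, unreadable entry)."""


class ValidationError(DesatsigError):
    """Record-level constraint violated (alphabet, uniqueness, coordinates)."""


class SchemaError(DesatsigError):
    """Tabular input does not match the expected column schema."""


class SpecError(DesatsigError):
    """A synthetic-data specification is internally inconsistent or infeasible."""


class UndefinedCorrelationError(DesatsigError):
    """Correlation requested on a series with zero variance or too few points."""
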