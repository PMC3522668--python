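"""Exception hierarchy shared across the package."""


class ZebraMHCError(Exception):
    """Base class for package errors."""


class AlignmentError(ZebraMHCError):
    """Ragged or otherwise invalid alignment."""


class FormatError(ZebraMHCError):
    """Malformed input file (duplicate IDs, bad cell syntax, ...)."""


class DataError(ZebraMHCError):
    """Data violating a domain constraint (e.g. >4 alleles in a multicopy cell)."""


class CrossReferenceError(ZebraMHCError):
    """A genotype call names an allele absent from the attached alignment."""


class ParameterError(ZebraMHCError):
    """Invalid argument value for a statistical operation."""


class ConvergenceError(ZebraMHCError):
    """An iterative estimator failed to converge."""


class UndefinedStatisticError(ZebraMHCError):
    """A statistic is undefined for the given input (e.g. no overlapping calls)."""


class ConfigurationError(ZebraMHCError):
    """Invalid or incomplete pipeline configuration/dataset."""
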