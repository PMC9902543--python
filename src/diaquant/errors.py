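"""Exception hierarchy for the pipeline.

Error classes map one-to-one onto CLI exit codes (see :mod:`diaquant.cli`):
configuration (2), file format (3), data integrity (4), numeric/size (5).
"""


class DiaQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(DiaQuantError):
    """Invalid parameter, threshold, or pipeline configuration."""


class FormatError(DiaQuantError):
    """Malformed or incomplete input file."""


class IntegrityError(DiaQuantError):
    """Inputs are well-formed but internally inconsistent."""


class NumericError(DiaQuantError):
    """A computation cannot proceed on the given data."""


class NormalizationError(NumericError):
    """Quantile normalization impossible (e.g. a run with no observations)."""


class ImputationError(NumericError):
    """Imputation impossible (e.g. no observed entries to anchor the quantile)."""


class SizeError(NumericError):
    """Too few rows/columns for the requested operation."""
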