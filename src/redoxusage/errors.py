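"""Typed exceptions raised across the package."""


class RedoxUsageError(Exception):
    """Base class for all package errors."""


class FormatError(RedoxUsageError):
    """Malformed external input (FASTA, TMHMM output, TSV, Newick)."""


class ConfigurationError(RedoxUsageError):
    """Invalid configuration value or inconsistent option set."""


class DataError(RedoxUsageError):
    """Semantically invalid data (out-of-bounds segment, empty pool, ...)."""
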