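"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError (and subclasses) to exit code 3.
"""


class KmersweepError(Exception):
    """Base class for all package errors."""


class ConfigError(KmersweepError):
    """Invalid configuration: duplicate sample ids, bad partitions, bad flags."""


class DataError(KmersweepError):
    """Invalid or corrupt input data."""


class ParseError(DataError):
    """Malformed FASTA/FASTQ input."""


class IndexCorruptionError(DataError):
    """Inconsistency detected inside a persisted or in-memory index."""
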