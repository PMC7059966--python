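"""Exception taxonomy.

The distinction that matters to callers (and to the CLI exit codes) is
between ordinary input/format problems and *provenance* problems — a
checksum that is missing, malformed, or inconsistent across samples.
"""


class TxprovError(Exception):
    """Base class for all errors raised by this package."""


class InputError(TxprovError):
    """A required input is missing or unusable (file not found, bad value)."""


class FormatError(TxprovError):
    """A file exists but does not conform to its expected format."""


class SchemaError(FormatError):
    """A tabular or JSON document is missing required columns/keys."""


class ProvenanceError(TxprovError):
    """Reference-transcriptome identity cannot be established or conflicts.

    Raised when the embedded index checksum is absent, malformed, or differs
    across samples that are being imported together.
    """


class IncompatibilityError(TxprovError):
    """Genomic ranges from different genome builds (or with inconsistent
    chromosomes) were combined."""


class CacheInvalidError(TxprovError):
    """A cached artifact was written by an incompatible version or is
    corrupted; re-parsing from the source is required."""
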