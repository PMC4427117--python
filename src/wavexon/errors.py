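"""Exception hierarchy.

Every error raised on a user-facing code path derives from :class:`WavexonError`
so the CLI can map it to an exit code: config/usage problems exit 1, data
problems (format or validation) exit 2, anything else exits 3.
"""


class WavexonError(Exception):
    """Base class for all package errors."""


class FormatError(WavexonError):
    """A file does not parse as the named format (FASTA/BED/GFF3/YAML)."""


class ValidationError(WavexonError):
    """Parsed content violates a contract (bad character, bad interval, ...)."""


class DegenerateInputError(WavexonError):
    """Input is structurally valid but the operation is undefined on it
    (all-zero profile, all-zero confusion counts, truth without negatives)."""


class ConfigError(WavexonError):
    """Pipeline configuration is invalid or contains unknown keys."""
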