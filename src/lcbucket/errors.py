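"""Exception hierarchy for the pipeline.

User-facing commands map ``UserInputError`` subclasses to exit code 1 and
anything else to 2.
"""


class LCBucketError(Exception):
    """Base class for all package errors."""


class UserInputError(LCBucketError):
    """Errors caused by invalid user input or files."""


class MzmlParseError(UserInputError):
    """Malformed or unreadable mzML file."""


class ProfileModeError(UserInputError):
    """Profile-mode spectra supplied where centroided data is required."""


class WindowMatchError(UserInputError):
    """MS2 precursor target does not match any acquisition-scheme window."""


class ManifestError(UserInputError):
    """Invalid sample manifest."""


class ConfigError(UserInputError):
    """Invalid configuration (simulator or pipeline)."""


class AlignmentError(LCBucketError):
    """Retention-time alignment failed (degenerate similarity)."""


class SchemaMismatchError(UserInputError):
    """Bucket schemas or reference hashes do not match."""
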