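"""Exception types used across the package."""


class CloneFateError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CloneFateError):
    """A configuration value violates its invariants."""


class FastqParseError(CloneFateError):
    """A FASTQ stream is malformed; carries the offending record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class UndefinedDiversityError(CloneFateError):
    """Shannon diversity requested for an all-zero count vector."""


class ClassificationError(CloneFateError):
    """A barcode is missing a statistic required by the decision tree."""
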