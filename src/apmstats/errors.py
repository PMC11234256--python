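"""Exception hierarchy.

All domain errors derive from :class:`ApmsError` so callers (and the CLI,
which maps them to exit code 1) can distinguish invalid input from genuine
runtime failures.
"""


class ApmsError(ValueError):
    """Base class for all validation and configuration errors."""


class LayoutError(ApmsError):
    """A plex layout is internally inconsistent or does not match the data."""


class BaitNotFoundError(ApmsError):
    """The declared bait protein is absent from the abundance table."""


class NormalizationError(ApmsError):
    """Bait abundance is zero or missing in an experimental channel."""


class ConfigurationError(ApmsError):
    """A rule or pipeline configuration conflicts with the experiment layout."""


class InsufficientReplicatesError(ApmsError):
    """A statistical test was requested with fewer than two values per group."""


class CoverageError(ApmsError):
    """A participant/genotype combination has no (or too few) images."""
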