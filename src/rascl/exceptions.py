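"""Exception taxonomy shared across the package."""


class RasclError(Exception):
    """Base class for package errors."""


class ConfigurationError(RasclError, ValueError):
    """Invalid configuration value or schema violation."""


class FormatError(RasclError, ValueError):
    """Unreadable or malformed on-disk data (TIFF pages, manifests)."""


class DomainError(RasclError, ValueError):
    """Arguments outside an operation's mathematical domain."""


class SamplingError(RasclError, ValueError):
    """Positive-pair sampling impossible (e.g. single-slice volume)."""


class BatchError(RasclError, ValueError):
    """A contrastive batch cannot be assembled from the eligible eyes."""


class CapacityError(RasclError, ValueError):
    """A split request exceeds the eyes available in some class."""
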