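"""Exception types shared across the package."""


class KinsertError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(KinsertError):
    """Raised when a run configuration or reference set is unusable."""


class ReferenceError_(KinsertError):
    """Raised when a named reference (flank, component, contig) is missing."""
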