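"""Exception hierarchy shared across the package."""


class PeerSelectError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PeerSelectError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class IntegrityError(PeerSelectError, ValueError):
    """A referential-integrity violation, e.g. an alter pointing at an unknown index."""


class ParseError(PeerSelectError, ValueError):
    """A malformed on-disk table; the message carries the line number when known."""


class SchemaError(PeerSelectError, ValueError):
    """Predictor sets or column schemas that do not line up across inputs."""


class DegenerateLabelError(PeerSelectError, ValueError):
    """A classification target with fewer than two classes."""
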