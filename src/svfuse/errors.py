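"""Exception hierarchy shared across the package."""


class SvFuseError(Exception):
    """Base class for all svfuse errors."""


class DataError(SvFuseError):
    """Malformed or inconsistent input data (exit code 3 at the CLI)."""


class ConfigError(SvFuseError):
    """Invalid configuration or schema violation (exit code 2 at the CLI)."""


class ModelVersionError(SvFuseError):
    """Model file schema id does not match what this version can load."""
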