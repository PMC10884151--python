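"""Exception hierarchy shared across the package."""


class TampolError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TampolError):
    """A CSV row or record violates the published schema or an invariant."""


class GenerationError(TampolError):
    """The synthetic-cohort generator could not satisfy its configuration."""


class ConfigError(TampolError):
    """A pipeline configuration is invalid or incomplete."""


class StageError(TampolError):
    """A pipeline stage failed; the message names the stage."""
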