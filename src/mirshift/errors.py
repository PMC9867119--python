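"""Exception hierarchy shared across the package."""


class MirshiftError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MirshiftError, ValueError):
    """A function was called with out-of-range or inconsistent parameters."""


class DataError(MirshiftError, ValueError):
    """Input data violate a contract (malformed file, negative counts, ...)."""


class PipelineError(MirshiftError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
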