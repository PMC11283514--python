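"""Exception types shared across the package."""


class GazekitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GazekitError, ValueError):
    """An object or value violates a domain invariant."""


class FormatError(GazekitError, ValueError):
    """An input file does not conform to the documented dialect."""


class PipelineError(GazekitError, RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""
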