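"""Exception hierarchy used across the pipeline."""


class LikError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LikError):
    """A file does not conform to its declared dialect."""


class DesignError(LikError):
    """The experiment design is inconsistent with the data or the request."""


class ParameterError(LikError):
    """Invalid simulation or analysis parameters."""


class InsufficientReplicationError(DesignError):
    """A statistical test was requested without the replicates it needs."""
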