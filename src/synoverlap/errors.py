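"""Exception hierarchy shared across the pipeline stages."""


class SynoverlapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SynoverlapError):
    """A configuration file, column map or chain declaration is invalid."""


class ValidationError(SynoverlapError):
    """Input data violates a stage precondition."""


class ParameterError(SynoverlapError):
    """A numeric or structural parameter is out of its admissible range."""


class FixtureError(SynoverlapError):
    """A packaged reference table fails its pinned consistency checks."""
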