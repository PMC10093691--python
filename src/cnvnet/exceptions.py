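"""Exception hierarchy shared by all cnvnet modules."""


class CNVNetError(Exception):
    """Base class for all package errors."""


class ParameterError(CNVNetError, ValueError):
    """A user-supplied parameter is out of its documented range."""


class ValidationError(CNVNetError, ValueError):
    """Inputs violate a documented precondition (shape, emptiness, labels)."""


class FormatError(CNVNetError, ValueError):
    """An on-disk artifact does not match the expected format."""


class ConfigurationError(CNVNetError, ValueError):
    """A model/run configuration is internally inconsistent."""


class TrainingError(CNVNetError, RuntimeError):
    """Training diverged or produced non-finite values."""
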