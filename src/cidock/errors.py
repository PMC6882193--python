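"""Exception hierarchy for the consensus inverse docking pipeline."""


class CidockError(Exception):
    """Base class for all package errors."""


class FormatError(CidockError):
    """A file could not be parsed in its declared dialect."""


class ContentError(CidockError):
    """A file parsed but its chemical content is unusable (e.g. no heavy atoms)."""


class TopologyError(CidockError):
    """Two molecules that must share topology do not."""


class MissingScoreError(CidockError):
    """No engine score could be attached to a pose."""


class SchemaError(CidockError):
    """A tabular input is missing required columns."""


class ValidationError(CidockError):
    """A record violates one of its defining identities or bounds."""


class ConfigError(CidockError):
    """An engine or run configuration is invalid."""


class EngineEnvironmentError(CidockError):
    """A requested external docking executable is unavailable."""


class EngineRunError(CidockError):
    """An external engine ran but failed or produced no poses."""


class UsageError(CidockError):
    """An operation was called with an unsupported combination of options."""
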