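"""Exception hierarchy shared across the pipeline stages."""


class NecromineError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NecromineError):
    """A column mapping, filter, or generator config is invalid."""


class CorpusLoadError(NecromineError):
    """The input file could not be turned into a corpus."""


class EmptyCorpusError(NecromineError):
    """An operation that needs at least one document got none."""


class UnknownVariableError(NecromineError):
    """A metadata role was requested that the corpus does not carry."""
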