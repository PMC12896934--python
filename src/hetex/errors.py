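"""Exception hierarchy shared across the package."""


class HetexError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HetexError, ValueError):
    """An invalid configuration object or config file."""


class FormatError(HetexError, ValueError):
    """A malformed input file or container (duplicate ids, bad columns, ...)."""


class UsageError(HetexError, ValueError):
    """An operation called with arguments violating its contract."""
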