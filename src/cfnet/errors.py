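"""Exception hierarchy for cfnet."""


class CfnetError(Exception):
    """Base class for all cfnet errors."""


class FormatError(CfnetError, ValueError):
    """A file did not conform to the expected dialect."""


class ConfigError(CfnetError, ValueError):
    """Invalid configuration or parameter value."""
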