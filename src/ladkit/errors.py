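"""Exception hierarchy for :mod:`ladkit`."""


class LadError(Exception):
    """Base class for all ladkit errors."""


class ConfigError(LadError):
    """The ruleset/configuration is structurally invalid or incomplete."""


class ValidationError(LadError):
    """An input value violates a precondition or physical constraint."""
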