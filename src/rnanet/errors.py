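"""Exception hierarchy shared by all pipeline stages.

Stages raise :class:`ValidationError` for semantically invalid inputs,
:class:`ParseError` for files that cannot be interpreted, and
:class:`ConfigurationError` for missing or malformed configuration keys.
The CLI maps these to exit code 2, and :class:`DependencyError` (a stage
run before its upstream producer) to exit code 3.
"""


class RnanetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RnanetError):
    """A mandatory configuration key is missing or malformed."""


class ValidationError(RnanetError):
    """Input data violates a documented invariant."""


class ParseError(RnanetError):
    """A file could not be parsed in the expected dialect."""


class DependencyError(RnanetError):
    """A pipeline stage was run before the stage that produces its input."""
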