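"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: :class:`FormatError` -> 2,
:class:`ConfigurationError` -> 3.
"""


class LncpopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LncpopError):
    """A parameter or configuration field is outside its documented range."""


class FormatError(LncpopError):
    """An input file violates the expected dialect (names file/line/field)."""


class InputError(LncpopError):
    """A value-level problem in otherwise well-formed input data."""


class InsufficientDataError(LncpopError):
    """Too few observations for the requested statistic."""
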