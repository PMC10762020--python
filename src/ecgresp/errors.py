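"""Exception hierarchy.

All package errors derive from :class:`EcgRespError` so callers can catch
one base class; the subclasses distinguish bad configuration, malformed
input files, and data that is structurally valid but unusable.
"""


class EcgRespError(Exception):
    """Base class for all ecgresp errors."""


class ConfigError(EcgRespError, ValueError):
    """A parameter value violates its documented constraints."""


class FormatError(EcgRespError, ValueError):
    """An input file cannot be decoded (truncated, non-numeric, ...)."""


class InputError(EcgRespError, ValueError):
    """Input data is well-formed but insufficient or unusable."""
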