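"""Exception hierarchy.

All library errors derive from :class:`GlycoscanError` so callers (and the
CLI) can distinguish bad input (exit code 2) from bad configuration
(exit code 3).
"""


class GlycoscanError(Exception):
    """Base class for all errors raised by glycoscan."""


class InputError(GlycoscanError):
    """Invalid user-supplied data (sequences, hit tables, catalogs)."""


class ParseError(InputError):
    """A file could not be parsed; the message names the offending record."""


class NoMatchColumnsError(InputError):
    """A seed alignment has no column meeting the match-column rule."""


class CalibrationError(GlycoscanError):
    """Gumbel calibration failed (e.g. degenerate score distribution)."""


class NotCalibratedError(GlycoscanError):
    """An E-value was requested from a model with no Gumbel parameters."""


class ConfigError(GlycoscanError):
    """Invalid pipeline or generator configuration."""
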