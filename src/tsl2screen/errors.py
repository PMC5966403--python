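"""Exception hierarchy for the tsl2screen pipeline.

Every stage raises a subclass of :class:`Tsl2ScreenError`, so callers
(including the CLI) can catch one type and report which stage and which
input was at fault.
"""


class Tsl2ScreenError(Exception):
    """Base class for all tsl2screen errors."""


class MissingControlError(Tsl2ScreenError):
    """A required control role (A/B/C/D well) is absent."""


class AssayWindowError(Tsl2ScreenError):
    """The RNA-dependent dye signal window (C - D) is too small to
    normalise against; the displacement ratio would be unstable."""


class DegenerateControlsError(Tsl2ScreenError):
    """Positive and negative control means coincide; the screening-window
    coefficient is undefined."""


class InsufficientDataError(Tsl2ScreenError):
    """Fewer observations than the statistic requires."""


class InsufficientDosesError(Tsl2ScreenError):
    """Fewer than four distinct concentrations for a 4PL fit."""


class UndefinedStatisticError(Tsl2ScreenError):
    """The requested statistic does not exist for this input (constant
    signal correlation, headroom-free %MIP, flat spectrum extremum...).
    Raised instead of returning NaN."""


class EnsembleFormatError(Tsl2ScreenError):
    """A structure ensemble violates the congruent-roster contract or is
    missing required atoms."""


class ConfigError(Tsl2ScreenError):
    """A pipeline or generator configuration is invalid; the message names
    the offending key."""
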