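"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`BLIError`
so callers (and the CLI) can distinguish analysis errors from bugs.
"""


class BLIError(Exception):
    """Base class for all blifit errors."""


class DomainError(BLIError, ValueError):
    """A numeric argument is outside its physical domain (names the field)."""


class UndefinedKDError(DomainError):
    """K_D = k_off / k_on requested with k_on = 0."""


class StructuralError(BLIError, ValueError):
    """Shapes or counts of a dataset / parameter vector are inconsistent."""


class DegenerateDesignError(BLIError, ValueError):
    """The concentration series cannot identify the kinetic rates
    (e.g. all curves at the same concentration)."""


class DegenerateScenarioError(BLIError, ValueError):
    """A simulation scenario is internally inconsistent
    (e.g. saturation amplitudes requested with k_on = 0)."""


class PerfectFitError(BLIError, ZeroDivisionError):
    """Normalized chi-squared requested with a zero optimum SSE.

    A zero SSE means the data are noiseless; profile thresholds are
    meaningless there. Use the noiseless round-trip checks instead of
    confidence intervals.
    """


class FitDivergenceError(BLIError, RuntimeError):
    """The model produced non-finite values during optimization."""


class InconsistentProfileError(BLIError, RuntimeError):
    """A profile scan lies entirely above the confidence threshold,
    i.e. the refits failed to reproduce the reported optimum."""


class ParseError(BLIError, ValueError):
    """A sensorgram or report file failed validation (names file and line)."""
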