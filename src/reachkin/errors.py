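"""Exception hierarchy for the reachkin pipeline."""


class ReachkinError(Exception):
    """Base class for all reachkin errors."""


class FormatError(ReachkinError):
    """A trial or report file does not conform to the expected dialect."""


class TrialValidationError(ReachkinError):
    """A trial violates a physical or structural invariant (range, monotonicity)."""


class NoMovementError(ReachkinError):
    """No significant movement could be located in the trial."""


class UnprocessableTrialError(ReachkinError):
    """The trial cannot be processed (e.g. a marker gap of >= 10 frames)."""


class UndefinedMetricError(ReachkinError):
    """A statistic is undefined for the given input (zero variance, all-zero signal)."""


class AlignmentError(ReachkinError):
    """Two time series that must share a time base do not overlap or mismatch in length."""
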