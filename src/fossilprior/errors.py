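"""Exception hierarchy.

Method failures (rate estimation, curve construction, distribution fitting)
are distinct classes so that the validation harness and the CLI can tally
them separately from plain input errors.
"""


class FossilPriorError(Exception):
    """Base class for all package-specific errors."""


class TimescaleError(FossilPriorError):
    """Invalid or unknown stratigraphic timescale."""


class RangeDataError(FossilPriorError):
    """Malformed fossil range or occurrence input."""


class RateEstimationFailure(FossilPriorError):
    """Too few bins with defined per-capita rates to average.

    Raised when the stratigraphic ranges are not sufficiently overlapping:
    fewer than two bins yield a defined origination rate, or fewer than two
    yield a defined extinction rate.
    """


class PreservationRateUndefined(FossilPriorError):
    """Range-frequency ratio is undefined (no singletons or no 3-bin ranges)."""


class CurveFailure(FossilPriorError):
    """The likelihood curve is identically zero (inconsistent inputs)."""


class FitFailure(FossilPriorError):
    """The least-squares gamma fit did not converge or its residual is too large.

    Carries the best (non-converged) prior found, if any, in ``prior``.
    """

    def __init__(self, message, prior=None):
        super().__init__(message)
        self.prior = prior
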