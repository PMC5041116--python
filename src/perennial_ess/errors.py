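"""Exception hierarchy for model-domain failures.

Everything raised deliberately by this package derives from :class:`ModelError`,
so callers can distinguish model-domain problems from programming errors.
"""


class ModelError(Exception):
    """Base class for all errors raised by perennial_ess."""


class DomainError(ModelError, ValueError):
    """An argument lies outside the mathematical domain of a curve or map."""


class DegeneratePollenPoolError(ModelError, ZeroDivisionError):
    """The resident produces no pollen while outcrossed ovules exist.

    The outcross-siring term needs the ratio m(M')/m(M); with resident M = 0
    and (1 - s)·f(F) > 0 that ratio is undefined.
    """


class BoundaryGradientError(ModelError):
    """A two-sided selection gradient was requested at a boundary resident."""


class UnboundedMarginalError(ModelError):
    """A marginal gain is unbounded (power male gain evaluated at M = 0)."""


class ZeroFemaleGainError(ModelError, ZeroDivisionError):
    """The threshold tau requires f(F) > 0 at the evaluation strategy."""


class ConvergenceError(ModelError):
    """Best-response iteration failed to converge within the iteration cap.

    Carries the iteration trajectory for diagnosis.
    """

    def __init__(self, message: str, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory if trajectory is not None else []


class InternalConsistencyError(ModelError):
    """Two supposedly equivalent computations disagree beyond tolerance.

    Raised by classify_mating_ess when the analytic rule (compare delta_j with
    1/2 - tau) and the sign of the numerically evaluated selection gradient
    disagree; this is a tripwire for implementation defects, not a user error.
    """


class CurveSupportError(ModelError, TypeError):
    """A closed-form solver was invoked with curves it does not support."""
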