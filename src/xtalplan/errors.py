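"""Exception hierarchy.

Validation failures (bad specs, malformed inputs) derive from
:class:`ValidationError`; failures of the numerics themselves (degenerate
regressions, unstable steps, runaway nucleation) derive from
:class:`NumericalError`.  The CLI maps these to exit codes 2 and 3.
"""


class XtalPlanError(Exception):
    """Base class for all package errors."""


class ValidationError(XtalPlanError, ValueError):
    """Invalid domain object or malformed input data."""


class InvalidSpecError(ValidationError):
    """A protein spec (or other physical spec) has a non-physical field."""


class InfeasibleBudgetError(ValidationError):
    """The requested crystal cannot be grown: concentration at or below solubility."""


class NumericalError(XtalPlanError):
    """A computation failed for numerical reasons."""


class DegenerateFitError(NumericalError):
    """The regression design is singular (e.g. all abscissae identical)."""


class InsufficientEventsError(NumericalError):
    """Fewer observations than the fit requires."""


class EmptyRegionError(NumericalError):
    """A data-window restriction excluded every point."""


class StepSizeError(NumericalError):
    """A depletion step drove the concentration significantly negative; reduce dt."""


class CapExceededError(NumericalError):
    """The simulated crystal count exceeded the configured cap."""
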