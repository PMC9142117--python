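"""Exception hierarchy for the ltued pipeline.

All pipeline errors derive from :class:`LtuedError` so callers (and the CLI)
can catch one base class; the subclasses distinguish bad configuration, bad
input data, and estimation failures.
"""


class LtuedError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(LtuedError, ValueError):
    """An invalid field in a generator or run configuration."""


class InputDataError(LtuedError, ValueError):
    """Input records or tables violate a precondition (missing column,
    missing ZCTA, nonpositive population, ...)."""


class EstimationError(LtuedError, RuntimeError):
    """A model fit failed: rank deficiency, separation, or non-convergence."""


class DegenerateDataError(EstimationError):
    """A predictor is constant or collinear, so the model is not identified."""
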