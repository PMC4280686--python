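"""Exception hierarchy.

All package-specific failures derive from :class:`CondPoissonError` so
callers (notably the CLI) can map classes of failure onto distinct exit
codes: data/configuration problems vs numerical/convergence problems.
"""


class CondPoissonError(Exception):
    """Base class for all condpoisson errors."""


class DataError(CondPoissonError):
    """Invalid input data or configuration (bad dates, missing columns,
    non-integral counts, missing covariate values, degenerate designs)."""


class NonIdentifiableError(CondPoissonError):
    """The within-stratum-centered design is rank deficient: one or more
    covariates carry no information once stratum baselines are eliminated."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


class ConvergenceError(CondPoissonError):
    """An iterative fit failed to converge (or diverged, e.g. complete
    separation). Carries the iteration trace for diagnosis."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


class StratumCapError(CondPoissonError):
    """The unconditional Poisson fitter refused a design whose stratum count
    exceeds the configured cap; use the conditional fitter instead."""
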