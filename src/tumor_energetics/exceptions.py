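"""Exception hierarchy for the tumor-energetics model."""


class TumorEnergeticsError(ValueError):
    """Base class for all model errors."""


class DomainError(TumorEnergeticsError):
    """An input lies outside the physical/mathematical domain of an operation."""


class UsageError(TumorEnergeticsError):
    """A structurally invalid call (empty grid, inverted range, too few records)."""


class SingularFitError(UsageError):
    """The regression design matrix is rank-deficient (e.g. constant predictor)."""


class DataConsistencyError(TumorEnergeticsError):
    """Inputs are individually valid but jointly contradictory."""


class DivergenceError(DomainError):
    """The recycling expectation diverges (infinite Cori recycling)."""
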