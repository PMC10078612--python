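"""Exception hierarchy used across the package."""


class TraitSyncError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TraitSyncError):
    """Malformed or inconsistent input data."""


class ConfigurationError(TraitSyncError):
    """Invalid option, unknown trait name, or bad pipeline configuration."""


class DegeneratePopulationError(TraitSyncError):
    """A population's series is degenerate (e.g. zero residual variance)."""

    def __init__(self, population_id: str, message: str):
        self.population_id = population_id
        super().__init__(f"population {population_id!r}: {message}")


class DegenerateRegressorError(DegeneratePopulationError):
    """A regressor (climate series) has no variance within a population."""


class UndefinedCVError(TraitSyncError):
    """Coefficient of variation is undefined (zero mean)."""


class OptimizationError(TraitSyncError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics or []
        super().__init__(message)


class BootstrapQualityError(TraitSyncError):
    """Too many parametric-bootstrap replicates failed to converge."""
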