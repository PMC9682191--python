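"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input object violates one of its documented invariants."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance.

    Carries the final infeasibility / residual in ``residual`` when the
    raising solver can report one.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class SchemaError(ValueError):
    """A serialized artifact has an unknown or incompatible schema version."""
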