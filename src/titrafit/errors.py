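"""Exception hierarchy used across the package."""


class TitrafitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TitrafitError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(TitrafitError, ValueError):
    """A tabular input file does not match its declared schema."""


class ExtrapolationError(TitrafitError, ValueError):
    """A correction would require evaluating a reference curve outside
    its measured range; extrapolation is never done silently."""


class ConvergenceError(TitrafitError, RuntimeError):
    """A numerical routine failed to converge; carries diagnostics."""


class FitError(TitrafitError, RuntimeError):
    """All optimisation attempts for a fit failed; carries per-start
    diagnostics."""


class UnidentifiableError(TitrafitError, RuntimeError):
    """The requested quantity is not identifiable from the data
    (e.g. saturation fraction at zero protein, flat-response gauge
    degeneracy)."""
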