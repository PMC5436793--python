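"""Package-wide exception types."""


class MFEPathError(Exception):
    """Base class for all package errors."""


class DimensionError(MFEPathError, ValueError):
    """CV-space dimensions or periodicity declarations do not match."""


class GeometryError(MFEPathError, ValueError):
    """Degenerate geometry: collinear dihedral atoms, zero-length tangent, ..."""


class GridFormatError(MFEPathError, ValueError):
    """Malformed grid-surface or path file. Carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class BoundsError(MFEPathError, ValueError):
    """Evaluation outside a non-periodic grid axis (no extrapolation)."""


class ConvergenceError(MFEPathError, RuntimeError):
    """Iterative solver (SHAKE, relaxation) failed to reach tolerance."""


class ThermostatError(MFEPathError, RuntimeError):
    """Kinetic temperature diverged during constrained dynamics."""


class GrowthStallError(MFEPathError, RuntimeError):
    """Path growth exceeded the max-snapshots guard before reaching the product."""


class DegenerateDirectionError(MFEPathError, ValueError):
    """Growth direction has (near-)zero norm: gradient cancels the product pull."""
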