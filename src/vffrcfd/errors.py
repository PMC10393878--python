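"""Exception hierarchy for the vffrcfd pipeline."""


class VffrError(Exception):
    """Base class for all package errors."""


class ValidationError(VffrError, ValueError):
    """An input violates a documented bound; the message names the bound."""


class GeometryError(VffrError):
    """A lumen surface is unusable (not watertight, multi-intersection cut...)."""


class STLParseError(VffrError):
    """Malformed STL input.

    Attributes
    ----------
    byte_offset : int
        Offset into the file at which the problem was detected.
    """

    def __init__(self, message: str, byte_offset: int = 0):
        super().__init__(f"{message} (byte offset {byte_offset})")
        self.byte_offset = byte_offset


class MeshingError(VffrError):
    """Volumetric meshing failed; carries the failing axial station if known."""

    def __init__(self, message: str, station: int | None = None):
        if station is not None:
            message = f"{message} (axial station {station})"
        super().__init__(message)
        self.station = station


class SolverError(VffrError):
    """Flow-solver failure."""


class NonConvergenceError(SolverError):
    """Residuals diverged or the iteration cap was exceeded with growth.

    Carries the residual history recorded up to the failure.
    """

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history


class PairingError(VffrError):
    """Two flow solutions that must share a mesh/geometry do not."""


class StatsError(VffrError, ValueError):
    """Degenerate or insufficient data for a statistical routine."""
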