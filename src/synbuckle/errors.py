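"""Exception hierarchy for synbuckle."""


class SynbuckleError(Exception):
    """Base class for all package errors."""


class InvalidResolutionError(SynbuckleError):
    """Mesh resolution incompatible with the requested domain size."""


class MeshQualityError(SynbuckleError):
    """Degenerate triangles, isolated vertices, or other mesh defects."""


class InwardOnlyError(SynbuckleError):
    """A negative height was found where the inward-only constraint requires h >= 0."""


class ConfigurationError(SynbuckleError):
    """Invalid scenario or run configuration (overlapping vesicles, unknown keys, ...)."""


class OverhangError(ConfigurationError):
    """Requested dome rim radius smaller than its depth: not representable as a height field."""


class NumericalFailureError(SynbuckleError):
    """Non-finite heights, energies, or gradients encountered during integration."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StagnationError(NumericalFailureError):
    """Adaptive timestep underflowed: the descent cannot make progress."""
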