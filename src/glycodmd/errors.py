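"""Exception and warning types shared across the package."""


class GlycoDMDError(Exception):
    """Base class for all package errors."""


class DegenerateParameterError(GlycoDMDError):
    """Kinetic parameters admit no finite, positive steady state."""


class IntegrationError(GlycoDMDError):
    """The fixed-step integrator produced a non-finite state."""


class EmbeddingError(GlycoDMDError):
    """Requested delay embedding is too deep for the available snapshots."""


class DegenerateDataError(GlycoDMDError):
    """Input data carry no usable signal (e.g. identically zero)."""


class RankTruncationWarning(UserWarning):
    """Requested rank exceeded the numerical rank of the data."""


class MarginalStabilityWarning(UserWarning):
    """An eigenvalue real part lies within tolerance of zero."""


class UnstableModeWarning(UserWarning):
    """A discrete eigenvalue lies outside the unit circle; forecasts grow."""
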