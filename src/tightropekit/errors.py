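"""Exception types shared across the toolkit."""


class TightropeError(Exception):
    """Base class for all toolkit errors."""


class InvalidParameterError(TightropeError, ValueError):
    """A parameter violates a documented precondition."""


class SchemaError(TightropeError, ValueError):
    """A tabular input does not match its declared schema."""


class FitFailureError(TightropeError, RuntimeError):
    """A nonlinear fit failed to converge or produced an invalid optimum.

    May carry a ``fallback`` attribute with a degraded-but-usable result.
    """

    def __init__(self, message: str, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class TooShortError(TightropeError, ValueError):
    """A trajectory or phase has too few frames for the requested analysis."""


class NoParticleError(TightropeError, RuntimeError):
    """No column of a kymograph passed the detection threshold."""
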