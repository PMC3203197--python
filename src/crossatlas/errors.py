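"""Exception types shared across the package."""


class CrossAtlasError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CrossAtlasError):
    """An input file does not conform to the expected table layout."""


class IntegrityError(CrossAtlasError):
    """Data violate an atlas invariant (negative sd, asymmetric edges, ...)."""


class CalibrationError(CrossAtlasError):
    """Adaptive threshold search failed to meet its success criterion."""

    def __init__(self, message, curve=None):
        super().__init__(message)
        # (t_target, mean_R) pairs evaluated before failure, for diagnostics
        self.curve = curve or []
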