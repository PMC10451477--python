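"""Exception types shared across the package."""


class LungSpectraError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(LungSpectraError, ValueError):
    """A configuration object violates its invariants."""


class MatrixFormatError(LungSpectraError, ValueError):
    """A delimited expression-matrix file could not be parsed."""


class FitError(LungSpectraError, RuntimeError):
    """A model failed to fit (divergence, degenerate data, ...)."""
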