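"""Exception hierarchy for robustpls."""


class RobustPLSError(Exception):
    """Base class for all robustpls errors."""


class ConfigurationError(RobustPLSError, ValueError):
    """An invalid configuration value (bad index, negative scale, ...)."""


class DimensionError(RobustPLSError, ValueError):
    """Incompatible array shapes or an out-of-range component count."""


class DegenerateDataError(RobustPLSError, ValueError):
    """Input data on which the requested estimator is undefined.

    Examples: a response with zero variance, an all-zero weight vector,
    or a singular cross-product matrix that cannot be inverted.
    """
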