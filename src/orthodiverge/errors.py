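"""Exception hierarchy shared across the package."""


class OrthodivergeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(OrthodivergeError):
    """Malformed input file (message names the offending line)."""


class ValidationError(OrthodivergeError):
    """Input violates a documented precondition or invariant."""


class UndefinedStatisticError(OrthodivergeError):
    """A statistic has an empty denominator (e.g. GC of an all-N sequence)."""


class SaturationError(OrthodivergeError):
    """A distance correction is undefined because the observed proportion
    exceeds the correction's domain (e.g. p >= 3/4 for Jukes-Cantor)."""
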