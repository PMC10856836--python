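"""Exception hierarchy for the plate-assay pipeline.

Every stage raises a subclass of :class:`PhenoscanError` so the CLI can
abort with the failing stage named.
"""


class PhenoscanError(Exception):
    """Base class for all phenoscan errors."""


class SizingError(PhenoscanError):
    """Image too small to hold the requested non-overlapping well grid."""


class ConfigurationError(PhenoscanError):
    """Invalid or incomplete run configuration / preset coverage."""


class DegenerateInputError(PhenoscanError):
    """Input carries no usable signal (all-black image, constant sample, ...)."""


class InfeasibleTargetError(PhenoscanError):
    """A preset target cannot be realized as physical pixel values."""


class RegistrationError(PhenoscanError):
    """Thermal-to-RGB registration found no usable correlation signal."""


class NormalizationError(PhenoscanError):
    """Control reference missing or zero; percent-of-control undefined."""


class UnbalancedDesignError(PhenoscanError):
    """Two-way ANOVA requires a balanced complete factorial design."""
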