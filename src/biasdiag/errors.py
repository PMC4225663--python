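"""Exception hierarchy used across the package."""


class BiasDiagError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BiasDiagError):
    """Raised when an input file cannot be parsed or violates format rules."""


class TreeError(BiasDiagError):
    """Raised for invalid tree operations (rooting, clade resolution, ...)."""


class AnalysisError(BiasDiagError):
    """Raised when an analysis precondition is not met (empty subsets, ...)."""
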