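"""Exception hierarchy shared across the package."""


class GradNFError(Exception):
    """Base class for all package-specific errors."""


class DesignError(GradNFError, ValueError):
    """Invalid run/block design (bad level multiset, rank deficiency, ...)."""


class ProtocolError(GradNFError, ValueError):
    """Input violates a protocol precondition (e.g. rest block too short)."""


class CalibrationError(GradNFError, ValueError):
    """Feedback calibration is unusable (non-positive localizer PSC, ...)."""


class DataError(GradNFError, ValueError):
    """Data does not match the design it is analysed against."""


class DegenerateDataError(GradNFError, ValueError):
    """Statistic undefined on this input (e.g. zero-variance differences)."""


class AggregationError(GradNFError, ValueError):
    """Group table cannot be assembled (missing design cell)."""
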