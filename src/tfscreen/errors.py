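"""Exception hierarchy shared across the pipeline stages."""


class TFScreenError(Exception):
    """Base class for all package errors."""


class DesignError(TFScreenError):
    """Invalid factor definition or empty/degenerate design."""


class SimulationError(TFScreenError):
    """Ground-truth surface violates positivity, or archetype map is invalid."""


class MeasureError(TFScreenError):
    """Degenerate readouts or missing control data."""


class ModelError(TFScreenError):
    """Rank-deficient design, extrapolation, or invalid fit request."""


class QueryError(TFScreenError):
    """Malformed database-style query constraint."""


class ReportError(TFScreenError):
    """Missing or duplicated cells / measures during export."""
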