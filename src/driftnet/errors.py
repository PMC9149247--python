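"""Exception hierarchy for the driftnet pipeline.

Every stage raises a subclass of :class:`DriftnetError` so that the CLI can
surface the failing stage and offending entity without pattern-matching
messages.
"""


class DriftnetError(Exception):
    """Base class for all driftnet errors."""


class ConfigurationError(DriftnetError):
    """Invalid column mapping, unknown method name, or bad config key."""


class EmptyAfterQCError(DriftnetError):
    """Quality control removed every record."""


class InsufficientOverlapError(DriftnetError):
    """No lag in the scan grid has enough pairwise-complete observations."""


class DegenerateSeriesError(DriftnetError):
    """A series is constant (zero variance) where variation is required."""


class RankDeficiencyError(DriftnetError):
    """Lagged design matrix is singular after listwise deletion."""

    def __init__(self, message: str, lag_order: int | None = None):
        super().__init__(message)
        self.lag_order = lag_order


class InsufficientSitesError(DriftnetError):
    """Fewer than two cities have usable windows."""


class ExportError(DriftnetError):
    """A network export cannot be completed (e.g. missing coordinates)."""
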