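"""Exception hierarchy for factbmap."""


class FactbmapError(Exception):
    """Base class for all package errors."""


class InvalidResponseError(FactbmapError):
    """An item response outside the 0-4 Likert range."""


class ManifestError(FactbmapError):
    """An item manifest violating the FACT-B structure."""


class MissingStateError(FactbmapError):
    """An EQ-5D-5L state absent from a (partial) value-set table."""


class InvalidBoundsError(FactbmapError):
    """Transform bounds that do not bracket the observed utilities."""


class TransformDomainError(FactbmapError):
    """A value on or outside (y_min, y_max) passed to the logistic transform."""


class SchemaError(FactbmapError):
    """A CSV or table missing required columns / malformed rows."""


class EmptyDesignError(FactbmapError):
    """No usable rows remain after applying the model's completeness rule."""


class CollinearityError(FactbmapError):
    """Rank-deficient design matrix."""


class DegenerateLikelihoodError(FactbmapError):
    """A likelihood with no interior maximum (e.g. every observation censored)."""


class ConvergenceError(FactbmapError):
    """An iterative fit that failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedPredictionError(FactbmapError):
    """Prediction requested for a profile missing a required covariate."""


class RegistryLookupError(FactbmapError, KeyError):
    """Unknown (method, model) pair in the published-coefficient registry."""


class DegenerateGroupsError(FactbmapError):
    """A grouped statistic asked for with fewer than two distinct groups."""


class UndefinedCorrelationError(FactbmapError):
    """Correlation-based fit statistics on a constant vector."""


class ConfigError(FactbmapError):
    """Invalid run or simulation configuration."""
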