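"""Exception types raised across the pipeline."""


class PolyScfvError(Exception):
    """Base class for all package errors."""


class AnnotationError(PolyScfvError):
    """Chain splitting, numbering, or CDR delimitation failed."""


class FeatureError(PolyScfvError):
    """Feature computation or assembly failed."""


class SplitError(PolyScfvError):
    """Stratified train/test split cannot be performed."""


class TrainError(PolyScfvError):
    """Model training cannot proceed (e.g. single-class labels)."""


class SelectionError(PolyScfvError):
    """Ensemble member selection is infeasible for the requested scheme."""


class ProviderUnavailable(PolyScfvError):
    """A sequence-embedding provider is not installed/registered."""
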