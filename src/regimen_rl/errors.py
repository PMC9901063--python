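"""Exception hierarchy shared across the pipeline."""


class RegimenRLError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RegimenRLError):
    """An invalid parameter value (probability outside [0,1], bad gamma, ...)."""


class SchemaError(RegimenRLError):
    """An input table is missing a required column or is otherwise malformed."""


class SizingError(RegimenRLError):
    """Too few patients (or trajectories) for the requested operation."""


class ModelDegenerateError(RegimenRLError):
    """A fitted model has no usable structure (e.g. no leaf survives pruning)."""


class RoutingError(RegimenRLError):
    """A visit cannot be routed through the state tree (missing feature value)."""


class CoverageError(RegimenRLError):
    """A logged action has zero probability under the behavior policy."""
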