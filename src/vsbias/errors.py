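"""Exception taxonomy used across the package."""


class VsBiasError(Exception):
    """Base class for all package errors."""


class ConfigError(VsBiasError):
    """An invalid configuration field; the message names the field."""


class DimensionError(VsBiasError):
    """A vector, grid or channel count has the wrong shape."""


class InputError(VsBiasError):
    """Required input data is missing or malformed (NaN coordinates, no descriptor...)."""


class TypingError(VsBiasError):
    """An atom-type code is absent from the type map; the message names the code."""


class SplitError(VsBiasError):
    """A train/test split cannot be constructed from the available molecules."""


class TrainingError(VsBiasError):
    """Model training preconditions violated (e.g. single-class training data)."""


class MetricError(VsBiasError):
    """A metric is undefined for the given inputs (e.g. AUC with one class)."""


class SchemaError(VsBiasError):
    """A manifest or config file is missing a required column or key."""
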