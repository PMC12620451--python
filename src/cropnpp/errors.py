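"""Named exceptions raised across the pipeline."""


class CropNppError(Exception):
    """Base class for all package errors."""


class UnknownIndexError(CropNppError):
    """An index name outside the 15 supported vegetation indices."""


class MissingBandError(CropNppError):
    """A band required by an index formula is absent from the stack."""


class ShapeMismatchError(CropNppError):
    """Two grids that must share a shape/georeference do not."""


class FeatureMismatchError(CropNppError):
    """Prediction-time features do not match the model's recorded feature order."""


class DegenerateBoundsError(CropNppError):
    """Empirical-FPAR stretch bounds collapse (max <= min)."""


class MissingMonthError(CropNppError):
    """A month required for the seasonal aggregation is absent."""


class TooFewStationsError(CropNppError):
    """Not enough stations for the requested interpolation method."""


class NegativePrecipitationError(CropNppError):
    """Precipitation input contains negative values."""


class ConfigError(CropNppError):
    """Pipeline configuration failed validation."""


class TrainingError(CropNppError):
    """Model training aborted (too few samples, non-finite loss, ...)."""
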