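"""Exception hierarchy shared across the pipeline."""


class CropGeobiaError(Exception):
    """Base class for all package errors."""


class ValidationError(CropGeobiaError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(CropGeobiaError, ValueError):
    """A configuration object is internally inconsistent."""


class RasterIOError(CropGeobiaError, IOError):
    """A raster file could not be read or written."""


class BandMappingError(RasterIOError):
    """The bands found on disk do not match the declared band set."""


class SchemaError(CropGeobiaError, ValueError):
    """A tabular input is missing required columns or contains bad rows."""


class TrainingError(CropGeobiaError, ValueError):
    """Supervised training data is insufficient (e.g. an empty class)."""
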