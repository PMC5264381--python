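"""Exception hierarchy shared across the pipeline stages."""


class BlastogradeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(BlastogradeError):
    """Invalid or inconsistent configuration values."""


class DegenerateInputError(BlastogradeError):
    """Input is structurally valid but carries no usable signal
    (constant image, empty region, mask too small for an offset)."""


class NoEmbryoFoundError(BlastogradeError):
    """Circular Hough accumulator has no peak above the vote threshold."""


class IcmNotFoundError(BlastogradeError):
    """No compact bright region detectable inside the embryo circle."""


class InsufficientDataError(BlastogradeError):
    """Too few rows for the requested statistical operation."""


class SchemaError(BlastogradeError):
    """Feature names or dimensions do not match the expected registry."""


class StratificationError(BlastogradeError):
    """A label class cannot be represented in every split."""


class DivergenceError(BlastogradeError):
    """Training loss became non-finite."""


class FeatureExtractionError(BlastogradeError):
    """A feature evaluated to a non-finite value."""
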