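"""Exception hierarchy for adexpose."""


class AdExposeError(Exception):
    """Base class for all adexpose errors."""


class ValidationError(AdExposeError):
    """An input value violates a documented precondition."""


class ConfigError(ValidationError):
    """A configuration object is invalid; the message names the field."""


class IngestError(AdExposeError):
    """A raw advertising record could not be ingested."""


class CategoryError(AdExposeError):
    """A fine food-category code has no coarse mapping."""


class ExposureError(AdExposeError):
    """Exposure estimation failed (unknown ad, empty stratum, zero population...)."""


class NutritionError(AdExposeError):
    """A nutrition table row is malformed or a profile cannot be classified."""


class CodingError(AdExposeError):
    """Technique-coding operation failed (no overlap, too few coders...)."""


class ReportError(AdExposeError):
    """A report could not be assembled from the given estimates."""
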