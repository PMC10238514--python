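"""Exception hierarchy shared across the package."""


class CatPainError(Exception):
    """Base class for all package-specific errors."""


class CanvasSizeError(CatPainError, ValueError):
    """Canvas smaller than the minimum supported face frame."""


class RegionError(CatPainError, KeyError):
    """Unknown facial region name or inconsistent region map."""


class ParameterError(CatPainError, ValueError):
    """Invalid numeric parameter (negative sd, sigma <= 0, ...)."""


class ValidationError(CatPainError, ValueError):
    """Malformed table contents; the message names the offending row."""


class DegenerateCohortError(CatPainError, ValueError):
    """A cohort operation met an empty class."""


class MismatchedImagesError(CatPainError, ValueError):
    """Two annotation tables do not cover the same image ids."""


class DegenerateGeometryError(CatPainError, ValueError):
    """Geometry that admits no similarity fit (e.g. coincident eye centers)."""


class ShapeError(CatPainError, ValueError):
    """Landmark array of the wrong cardinality or layout."""


class SchemeError(CatPainError, ValueError):
    """Vector scheme violating its invariants (cross-region pair, duplicate)."""


class EmptyFeatureError(CatPainError, ValueError):
    """An occlusion configuration left zero features."""


class FoldError(CatPainError, ValueError):
    """Impossible fold plan (fewer subjects than folds, duplicates)."""


class LeakageError(CatPainError, RuntimeError):
    """A subject appeared in both train and test sides of a fold."""


class BoundsError(CatPainError, ValueError):
    """Landmark outside the raster it is read from or drawn on."""


class TaggingError(CatPainError, ValueError):
    """Feature without the landmark/region tags an aggregation needs."""


class CapabilityError(CatPainError, TypeError):
    """Model lacks the structure an explainability method requires."""
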