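"""Exception hierarchy shared across the package."""


class LVStrainError(Exception):
    """Base class for all package errors."""


class StudyFormatError(LVStrainError):
    """A contour study file is malformed (parse-level problem)."""


class StudyValidationError(LVStrainError):
    """A parsed study violates a structural invariant."""


class GeometryError(LVStrainError):
    """A polygon or perimeter input is geometrically degenerate."""


class TimingError(LVStrainError):
    """Frame times are missing, non-increasing, or inconsistent."""


class DataError(LVStrainError):
    """Required data (contour, layer, territory, covariate) is absent."""


class ParameterError(LVStrainError):
    """A user-supplied parameter is out of its valid range."""


class AggregationError(LVStrainError):
    """Strain curves with incompatible metadata were mixed."""


class SpecError(LVStrainError):
    """A synthetic-data specification is internally inconsistent."""


class PipelineError(LVStrainError):
    """An end-to-end pipeline stage failed."""
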