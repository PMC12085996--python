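"""Exception hierarchy for the roicell pipeline.

Every stage raises a subclass of :class:`RoiCellError` so callers (and the
CLI) can catch pipeline failures without masking programming errors.
"""


class RoiCellError(Exception):
    """Base class for all roicell errors."""


class FormatError(RoiCellError):
    """Input file decodes but does not have the expected layout."""


class EmptyRoiError(RoiCellError):
    """No region of interest could be found in an image."""


class ConfigurationError(RoiCellError):
    """Invalid run configuration or unknown backend/option."""


class ContractError(RoiCellError):
    """Two inputs that must be consistent (e.g. image and mask shape) are not."""


class EmptyInputError(RoiCellError):
    """An operation that needs at least one record received none."""


class FitError(RoiCellError):
    """A statistical model could not be fitted to the data provided."""


class InsufficientPointsError(RoiCellError):
    """A point-pattern mark has too few points for the requested statistic."""


class ParameterError(RoiCellError):
    """A numeric parameter is outside its valid range."""


class MappingError(RoiCellError):
    """A probe-to-gene (or similar) mapping is incomplete."""


class NormalizationError(RoiCellError):
    """Normalization factors are undefined (e.g. zero upper quartile)."""


class InsufficientReplicatesError(RoiCellError):
    """Too few segments/replicates to compute a correlation."""
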