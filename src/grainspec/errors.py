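"""Exception hierarchy for the grainspec pipeline.

Every stage raises a subclass of :class:`GrainspecError` so the CLI can map
failures to exit codes (2 for validation problems, 1 for stage failures).
"""


class GrainspecError(Exception):
    """Base class for all grainspec errors."""


class ConfigurationError(GrainspecError):
    """A configuration object violates its invariants."""


class CalibrationError(GrainspecError):
    """White minus dark reference is non-positive at some pixel/band."""


class SegmentationError(GrainspecError):
    """Grain segmentation produced an empty mask."""


class ExtractionError(GrainspecError):
    """A sample has no pixels under the grain mask."""


class CapacityError(GrainspecError):
    """Scene too small for the requested grain count."""


class DegenerateSpectrumError(GrainspecError):
    """A per-spectrum transform hit a constant (zero-variance) spectrum."""


class ScatterCorrectionError(GrainspecError):
    """MSC regression slope is numerically zero."""


class DegenerateModelError(GrainspecError):
    """A fitted model explains no variance (VIP undefined) or has no signal."""


class SelectionError(GrainspecError):
    """Wavelength selection returned an empty set."""


class ClassSizeError(GrainspecError):
    """A class has too few training samples to fit."""


class ClusteringError(GrainspecError):
    """K-means left an empty cluster after restarts."""


class EmptyPanelError(GrainspecError):
    """Genotype QC removed every marker."""


class DimensionError(GrainspecError):
    """Requested more principal components than samples allow."""


class KinshipError(GrainspecError):
    """Kinship matrix is not positive semi-definite."""


class AlignmentError(GrainspecError):
    """Sample identifiers do not line up across inputs."""


class CoordinateError(GrainspecError):
    """A marker position lies beyond its chromosome length."""


class ContractError(GrainspecError):
    """An input violated a documented ordering/sortedness contract."""


class NamingError(GrainspecError):
    """Chromosome naming mismatch between annotation and genotypes."""
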