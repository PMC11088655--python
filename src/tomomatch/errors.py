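"""Exception hierarchy.

Everything raised intentionally by tomomatch derives from
:class:`TomomatchError`, so callers (and the CLI) can catch one type.
"""


class TomomatchError(Exception):
    """Base class for all tomomatch errors."""


class FormatError(TomomatchError):
    """A file could not be parsed in the expected on-disk format."""


class DimensionalityError(FormatError):
    """A volume file does not contain 3D data."""


class SchemaError(FormatError):
    """A tabular file is missing required columns."""


class UnitError(TomomatchError):
    """Quantities with incompatible units were combined (voxels vs nm)."""


class DomainError(TomomatchError, ValueError):
    """A parameter is outside its valid domain."""


class ShapeError(TomomatchError):
    """Array shapes are incompatible (non-cubic grid, box too large, ...)."""


class MaskError(TomomatchError):
    """A mask is empty or unusable after processing."""


class ThresholdError(TomomatchError):
    """A density threshold selects no voxels."""


class HullError(TomomatchError):
    """A convex hull cannot be constructed (degenerate point set)."""


class DegenerateMapError(TomomatchError):
    """A score map has zero variance; z-scores are undefined."""


class DegenerateFitError(TomomatchError):
    """A mixture fit collapsed (identical data or vanishing variance)."""


class PackingError(TomomatchError):
    """Particles could not be placed without overlap."""
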