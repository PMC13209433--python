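"""Exception hierarchy.

Every error raised by the package derives from :class:`ShapedockError` so
callers can catch the whole family at pipeline boundaries.
"""


class ShapedockError(Exception):
    """Base class for all package errors."""


class FormatError(ShapedockError):
    """Unsupported or malformed structure file format."""


class EmptyStructureError(ShapedockError):
    """A structure file parsed to zero atoms."""


class ElementResolutionError(ShapedockError):
    """An element symbol could not be resolved in the radius table."""


class DegenerateGridError(ShapedockError):
    """Voxelization produced no occupied voxels."""


class DegenerateShapeError(ShapedockError):
    """Shape too small for the requested descriptor (e.g. single voxel)."""


class MetadataMismatchError(ShapedockError):
    """Descriptor vectors computed under incompatible settings."""


class MissingTopologyError(ShapedockError):
    """Bond information required but absent."""


class LibraryError(ShapedockError):
    """Descriptor-library build or search failure."""


class GenerationError(ShapedockError):
    """Conformer generation adapter failure."""


class EngineError(ShapedockError):
    """Docking engine invocation or output-parsing failure."""


class ConsistencyError(ShapedockError):
    """Cross-referenced records do not match (orphan docking result etc.)."""


class UndefinedMetricError(ShapedockError):
    """Screening metric undefined for the given labels (e.g. one class only)."""


class CoverageError(ShapedockError):
    """A query's designated true target is absent from the library."""
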