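"""Structured exceptions shared across the package."""


class VoxAtlasError(Exception):
    """Base class for all package errors."""


class OntologyError(VoxAtlasError):
    """Malformed region hierarchy: duplicate ids, orphans, cycles."""


class GeometryError(VoxAtlasError):
    """Slice geometry does not intersect the volume, or search grid empty."""


class ScalingError(VoxAtlasError):
    """Inconsistent scaling configuration (e.g. target below fixed mass)."""


class MappingError(VoxAtlasError):
    """Probability-map construction failure (missing rows, empty gene sets)."""
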