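"""Exception hierarchy shared across the pipeline stages."""


class VoxconnError(Exception):
    """Base class for all package errors."""


class ConfigError(VoxconnError):
    """A configuration object violates its invariants."""


class GridFormatError(VoxconnError):
    """A volumetric file does not match its declared shape or encoding."""


class StructureGraphError(VoxconnError):
    """The structure graph is not a tree (cycle, missing parent, no root)."""


class SchemaError(VoxconnError):
    """A persisted database does not carry the expected schema version."""


class EmptyRegionError(VoxconnError):
    """An operation needs voxels from a region that has none."""


class MissingArtifactError(VoxconnError):
    """A pipeline stage was invoked before its upstream stage produced output."""
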