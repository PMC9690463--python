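"""Exception types shared across the package."""


class MetaQTLError(Exception):
    """Base class for all package errors."""


class MapFormatError(MetaQTLError):
    """A linkage-map file violates the 3-column format or its invariants."""


class CatalogFormatError(MetaQTLError):
    """A QTL table is missing required columns or is otherwise unreadable."""


class ChromosomeExclusionError(MetaQTLError):
    """A chromosome cannot be linked: fewer than two common markers."""


class ProjectionError(MetaQTLError):
    """A position cannot be transferred onto the consensus map."""


class ModelError(MetaQTLError):
    """Invalid mixture-model request (e.g. more components than points)."""
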