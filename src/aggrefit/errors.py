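"""Exception hierarchy for aggrefit."""


class AggrefitError(Exception):
    """Base class for all aggrefit-specific errors."""


class ParseError(AggrefitError, ValueError):
    """A point-cloud or mesh file could not be parsed."""


class DegenerateCloudError(AggrefitError, ValueError):
    """The cloud has zero extent (e.g. all points identical)."""


class OutOfBoundsError(AggrefitError, ValueError):
    """A point falls outside the voxel-grid bounds."""


class ConfigurationError(AggrefitError, ValueError):
    """Inconsistent configuration (e.g. color predicate on a colorless cloud)."""


class EmptyCloudError(AggrefitError, ValueError):
    """An operation produced or received a cloud with no points."""


class EmptyClusterError(AggrefitError, ValueError):
    """A requested cluster contains no points."""


class PackingError(AggrefitError, RuntimeError):
    """Component packing failed; try fewer or smaller components."""


class MeshNotWatertightError(AggrefitError, ValueError):
    """Inside/outside queries require a watertight (closed, manifold) mesh."""
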