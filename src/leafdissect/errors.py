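"""Exception hierarchy for the leaf-dissection pipeline.

Every stage raises a dedicated subclass so batch drivers can isolate
per-leaf failures and report them in a QC table instead of aborting.
"""


class LeafPipelineError(Exception):
    """Base class for all pipeline errors."""


class SyntheticSpecError(LeafPipelineError, ValueError):
    """A synthetic-leaf specification violates one of its invariants."""


class InputImageError(LeafPipelineError, ValueError):
    """The input file is unreadable, not an image, or too small."""


class NoForegroundError(LeafPipelineError):
    """Binarization found no plausible foreground component."""


class EmptyMaskError(LeafPipelineError, ValueError):
    """An operation that requires foreground pixels received an empty mask."""


class PruningCollapseError(LeafPipelineError):
    """Branch pruning would delete the entire skeleton."""


class TopologyError(LeafPipelineError):
    """The skeleton graph lacks the topology an operation requires
    (e.g. no degree-1 node from which to pick the base)."""


class DegenerateClusterError(LeafPipelineError):
    """Skeleton distance values carry no blade/stem contrast."""


class BoundaryCutError(LeafPipelineError):
    """No outline point satisfies the opposite-side constraint for b2."""


class DissectionError(LeafPipelineError):
    """A chord cut failed to separate exactly the intended leaflet."""


class LandmarkError(LeafPipelineError):
    """A landmark construction line failed to intersect the outline."""


class DegenerateAxisError(LeafPipelineError, ValueError):
    """Base and top point coincide; the leaf axis is undefined."""
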