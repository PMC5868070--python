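"""End-to-end per-leaf processing: binarize → skeleton → dissect →
features → landmarks → markers.

The pipeline is deliberately stateless: :func:`analyze_mask` takes a
boolean mask (so synthetic ground-truth masks can bypass binarization)
and :func:`analyze_image` runs the full chain from a scan file.  Both
return a :class:`LeafResult` bundling every intermediate product, which
the CLI, the population module and the test-suite all consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import binarize as _bin
from . import dissect as _dis
from . import landmarks as _lm
from . import skeleton as _sk
from .dissect import CutNodeSet, LeafDissection
from .errors import LandmarkError
from .features import LeafFeatures, collect_leaf_features
from .landmarks import LandmarkSet, OutlineTrace
from .population import MarkerPointSet, normalize_leaf
from .skeleton import SkeletonGraph

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "LeafResult", "analyze_mask", "analyze_image"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the per-leaf pipeline.

    ``scale_factor`` is applied at load time (default 25%);
    ``prune_threshold_px`` is the minimum skeleton branch length kept
    (default 25 px at the working scale); ``orientation`` rotates the
    input by a multiple of 90° counterclockwise before processing, for
    scans that were not taken petiole-down.
    """

    scale_factor: float = 0.25
    prune_threshold_px: int = 25
    hole_area: int = 25
    dpi: float | None = None
    orientation: int = 0  # 0/90/180/270 degrees CCW
    seed: int = 0
    foreground: str = "saturated"

    def __post_init__(self):
        if not (0 < self.scale_factor <= 1):
            raise ValueError("scale_factor must be in (0, 1]")
        if self.prune_threshold_px < 0:
            raise ValueError("prune_threshold_px must be >= 0")
        if self.orientation % 90 != 0:
            raise ValueError("orientation must be a multiple of 90 degrees")


@dataclass
class LeafResult:
    """Everything the pipeline derives from one leaf."""

    leaf_id: str
    mask: np.ndarray
    graph: SkeletonGraph
    base: tuple[int, int]
    cuts: CutNodeSet
    dissection: LeafDissection
    features: LeafFeatures
    landmarks: LandmarkSet | None = None
    terminal_outline: OutlineTrace | None = None
    markers: MarkerPointSet | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_leaflets(self) -> int:
        return self.dissection.n_leaflets


def _rc_to_xy(p, height: int) -> tuple[float, float]:
    """Image (row, col) -> upright Cartesian (x, y up)."""
    return (float(p[1]), float(height - p[0]))


def analyze_mask(
    mask: np.ndarray,
    config: PipelineConfig | None = None,
    leaf_id: str = "leaf",
    source: str | None = None,
) -> LeafResult:
    """Run skeletonization, dissection, features and landmarks on a
    binary leaf mask."""
    config = config or PipelineConfig()
    mask = np.asarray(mask, dtype=bool)
    warnings_list: list[str] = []

    dist = _sk.distance_transform(mask)
    skel = _sk.skeletonize(mask)
    skel = _sk.prune_skeleton(skel, dist, config.prune_threshold_px)
    graph = _sk.build_graph(skel, dist)
    base = _sk.find_base_node(graph)

    labeling = _dis.cluster_distance_values(graph, random_state=config.seed)
    cuts = _dis.find_cut_nodes(graph, labeling, base)
    _dis.attach_boundary_pairs(mask, cuts, base=base)
    dissection = _dis.dissect(mask, graph, cuts, base)
    _dis.order_leaflets(dissection, graph)
    for lc in cuts.leaflets:
        if lc.flagged:
            warnings_list.append(lc.flagged)

    features = collect_leaf_features(
        leaf_id, mask, graph, dissection, cuts,
        dpi=config.dpi, scale_factor=config.scale_factor, source=source,
    )

    landmarks = None
    outline = None
    markers = None
    height = mask.shape[0]
    term = dissection.terminal_index
    try:
        term_mask = dissection.leaflet_mask(term)
        outline = _lm.outline_trace(term_mask)
        top = _lm.terminal_top_point(outline, base, cuts.leaflets[term].cut)
        landmarks = _lm.place_landmarks(
            outline, base, top, leaf_id=leaf_id, image_height=height
        )
        outline = _lm.rotate_to_start(outline, top)
    except LandmarkError as exc:
        warnings_list.append(f"landmarks: {exc}")

    # marker points for the metaleaf, in upright Cartesian coordinates
    try:
        centers = []
        for i, lc in enumerate(dissection.cuts.leaflets):
            if lc.flagged is not None:
                continue
            m = dissection.leaflet_mask(i)
            if m.any():
                rr, cc = np.nonzero(m)
                centers.append(_rc_to_xy((rr.mean(), cc.mean()), height))
        raw = {
            "leaflet_center": np.asarray(centers, dtype=float).reshape(-1, 2),
            "cut": np.asarray(
                [_rc_to_xy(lc.cut, height) for lc in cuts.leaflets if lc.flagged is None]
            ),
            "branching": np.asarray(
                [
                    _rc_to_xy(lc.branching, height)
                    for lc in cuts.leaflets
                    if lc.flagged is None
                ]
            ),
            "base": np.asarray([_rc_to_xy(base, height)]),
        }
        if landmarks is not None:
            top_pt = landmarks.points[0]
            raw["top"] = np.asarray([_rc_to_xy(top_pt, height)])
            markers = normalize_leaf(
                raw, _rc_to_xy(base, height), _rc_to_xy(top_pt, height), leaf_id=leaf_id
            )
    except Exception as exc:  # markers are auxiliary; never fail the leaf
        warnings_list.append(f"markers: {exc}")

    return LeafResult(
        leaf_id=leaf_id,
        mask=mask,
        graph=graph,
        base=base,
        cuts=cuts,
        dissection=dissection,
        features=features,
        landmarks=landmarks,
        terminal_outline=outline,
        markers=markers,
        warnings=warnings_list,
    )



def analyze_image(
    path,
    config: PipelineConfig | None = None,
    leaf_id: str | None = None,
) -> LeafResult:
    """Full pipeline from an image file on disk."""
    config = config or PipelineConfig()
    img = _bin.load_and_rescale(path, config.scale_factor, dpi=config.dpi)
    pixels = img.pixels
    if config.orientation % 360:
        pixels = np.rot90(pixels, k=(config.orientation // 90) % 4)
    mask = _bin.binarize(
        pixels,
        random_state=config.seed,
        hole_area=config.hole_area,
        foreground=config.foreground,
    )
    lid = leaf_id or str(path)
    return analyze_mask(mask, config, leaf_id=lid, source=str(path))
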