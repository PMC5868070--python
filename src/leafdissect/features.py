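"""Morphometric feature extraction for whole leaves and per-leaflet units.

Shape features follow the moment-equivalent-ellipse convention: the
leaflet's pixel coordinates define an empirical covariance matrix whose
eigenvalues give the semi-axes of an ellipse with the same normalized
second central moments; eccentricity is e = sqrt(1 - b²/a²) with a the
major and b the minor axis length.  Axis features (petiolule, rachis,
inter-rachis, base-to-branching) are measured along skeleton-graph
paths: the primary value is the Euclidean chain length of the path
(1 per axial step, √2 per diagonal step), with the raw node count also
reported.  Pixel→mm conversion uses the effective dpi, i.e. scanner
dpi × load-time scale factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .dissect import CutNodeSet, LeafDissection
from .skeleton import SkeletonGraph, path_chain_length

log = logging.getLogger(__name__)

__all__ = [
    "LeafletFeatures",
    "LeafFeatures",
    "FeatureTable",
    "leaflet_shape_features",
    "axis_features",
    "whole_leaf_features",
    "write_feature_table",
    "read_feature_table",
    "MM_PER_INCH",
]

MM_PER_INCH = 25.4


@dataclass
class LeafletFeatures:
    """Shape and position features of one leaflet (pixel units)."""

    rank: int | None = None
    side: str | None = None
    area: float = np.nan
    perimeter: float = np.nan
    major_axis: float = np.nan
    minor_axis: float = np.nan
    eccentricity: float = np.nan
    equivalent_diameter: float = np.nan
    petiolule_length: float = np.nan
    petiolule_node_count: float = np.nan
    base_to_branching: float = np.nan
    inter_rachis: float = np.nan  # to next same-side branching toward apex


@dataclass
class LeafFeatures:
    """One leaf's global features plus its per-leaflet rows."""

    leaf_id: str
    area: float = np.nan
    perimeter: float = np.nan
    rachis_length: float = np.nan
    rachis_node_count: float = np.nan
    petiole_length: float = np.nan
    n_leaflets: int = 0
    leaflets: list[LeafletFeatures] = field(default_factory=list)
    dpi: float | None = None
    scale_factor: float | None = None
    source: str | None = None


def leaflet_shape_features(leaflet_mask: np.ndarray) -> LeafletFeatures:
    """Moment-based shape features of a single connected pixel set.

    A single-pixel (or otherwise degenerate) mask yields zero axes and
    eccentricity 0 with a warning rather than an error.
    """
    leaflet_mask = np.asarray(leaflet_mask, dtype=bool)
    if not leaflet_mask.any():
        raise ValueError("leaflet mask is empty")
    props = regionprops(cc_label(leaflet_mask, connectivity=2))
    # largest region if the mask is accidentally fragmented
    p = max(props, key=lambda q: q.area)
    area = float(p.area)
    a = float(p.axis_major_length) / 2.0
    b = float(p.axis_minor_length) / 2.0
    if a <= 0 or b <= 0:
        log.warning("degenerate leaflet (area %d px): eccentricity reported as 0", p.area)
        ecc = 0.0
    else:
        ecc = math.sqrt(max(0.0, 1.0 - (b * b) / (a * a)))
    return LeafletFeatures(
        area=area,
        perimeter=float(p.perimeter),
        major_axis=2 * a,
        minor_axis=2 * b,
        eccentricity=ecc,
        equivalent_diameter=math.sqrt(4.0 * area / math.pi),
    )


def whole_leaf_features(mask: np.ndarray) -> tuple[float, float]:
    """(area, perimeter) of the whole-leaf mask in pixel units."""
    mask = np.asarray(mask, dtype=bool)
    props = regionprops(cc_label(mask, connectivity=2))
    p = max(props, key=lambda q: q.area)
    return float(p.area), float(p.perimeter)


def axis_features(
    graph: SkeletonGraph,
    dissection: LeafDissection,
    cuts: CutNodeSet,
) -> dict:
    """Axis measurements along skeleton paths.

    Returns a dict with ``rachis_length`` (base → terminal cut node),
    ``rachis_node_count``, ``petiole_length`` (base → first branching
    node) and, per leaflet index, ``petiolule_length``,
    ``petiolule_node_count``, ``base_to_branching`` and
    ``inter_rachis`` (missing → NaN, never 0).
    """
    base = graph.base_node
    term = dissection.terminal_index
    out: dict = {"per_leaflet": {}}

    term_path = graph.path(base, cuts.leaflets[term].cut)
    out["rachis_length"] = path_chain_length(term_path)
    out["rachis_node_count"] = float(len(term_path))

    branchings = [
        lc.branching
        for lc in cuts.leaflets
        if lc.flagged is None and lc.branching != base
    ]
    if branchings:
        first = min(
            branchings, key=lambda b: nx.shortest_path_length(graph.graph, base, b)
        )
        out["petiole_length"] = path_chain_length(graph.path(base, first))
    else:
        out["petiole_length"] = path_chain_length(term_path)  # simple leaf

    # same-side neighbor lookup for inter-rachis spans
    by_side: dict[str, list[tuple[int, float]]] = {"left": [], "right": []}
    for i, lc in enumerate(cuts.leaflets):
        if lc.flagged is not None or lc.rank in (None, 0):
            continue
        dist = nx.shortest_path_length(
            graph.graph, lc.branching, cuts.leaflets[term].branching
        )
        by_side.setdefault(lc.side, []).append((i, dist))
    for side in by_side:
        by_side[side].sort(key=lambda t: t[1])

    for i, lc in enumerate(cuts.leaflets):
        if lc.flagged is not None:
            continue
        rec: dict = {}
        pet_path = graph.path(lc.branching, lc.cut)
        rec["petiolule_length"] = path_chain_length(pet_path)
        rec["petiolule_node_count"] = float(len(pet_path))
        rec["base_to_branching"] = (
            path_chain_length(graph.path(base, lc.branching))
            if lc.branching != base
            else np.nan
        )
        rec["inter_rachis"] = np.nan
        if lc.side in ("left", "right"):
            ranked = by_side[lc.side]
            pos = next(j for j, (idx, _) in enumerate(ranked) if idx == i)
            if pos > 0:  # a same-side neighbor closer to the apex exists
                nbr = cuts.leaflets[ranked[pos - 1][0]]
                rec["inter_rachis"] = path_chain_length(
                    graph.path(lc.branching, nbr.branching)
                )
        out["per_leaflet"][i] = rec
    return out


def collect_leaf_features(
    leaf_id: str,
    mask: np.ndarray,
    graph: SkeletonGraph,
    dissection: LeafDissection,
    cuts: CutNodeSet,
    dpi: float | None = None,
    scale_factor: float | None = None,
    source: str | None = None,
) -> LeafFeatures:
    """Assemble the full feature record for one dissected leaf."""
    area, perim = whole_leaf_features(mask)
    ax = axis_features(graph, dissection, cuts)
    lf = LeafFeatures(
        leaf_id=leaf_id,
        area=area,
        perimeter=perim,
        rachis_length=ax["rachis_length"],
        rachis_node_count=ax["rachis_node_count"],
        petiole_length=ax["petiole_length"],
        dpi=dpi,
        scale_factor=scale_factor,
        source=source,
    )
    for i, lc in enumerate(cuts.leaflets):
        if lc.flagged is not None:
            continue
        lmask = dissection.leaflet_mask(i)
        if not lmask.any():
            continue
        feats = leaflet_shape_features(lmask)
        feats.rank = lc.rank
        feats.side = lc.side
        rec = ax["per_leaflet"].get(i, {})
        feats.petiolule_length = rec.get("petiolule_length", np.nan)
        feats.petiolule_node_count = rec.get("petiolule_node_count", np.nan)
        feats.base_to_branching = rec.get("base_to_branching", np.nan)
        feats.inter_rachis = rec.get("inter_rachis", np.nan)
        lf.leaflets.append(feats)
    lf.n_leaflets = len(lf.leaflets)
    return lf


class FeatureTable:
    """Long-format feature table: one row per (leaf, unit).

    Units are ``leaf`` (whole-leaf row) and ``leaflet``.  Lengths are
    pixels; if a dpi is known, ``*_mm``/``*_mm2`` columns are added
    using the effective dpi (scanner dpi × scale factor).
    """

    #: stable column order of the serialized table
    COLUMNS = [
        "leaf_id",
        "unit",
        "rank",
        "side",
        "area_px2",
        "perimeter_px",
        "major_axis_px",
        "minor_axis_px",
        "eccentricity",
        "equivalent_diameter_px",
        "petiolule_length_px",
        "petiolule_node_count",
        "base_to_branching_px",
        "inter_rachis_px",
        "rachis_length_px",
        "rachis_node_count",
        "petiole_length_px",
        "n_leaflets",
        "area_mm2",
        "perimeter_mm",
        "dpi",
        "scale_factor",
        "source",
    ]

    def __init__(self, leaves: list[LeafFeatures] | None = None):
        self.leaves: list[LeafFeatures] = list(leaves or [])

    def append(self, leaf: LeafFeatures) -> None:
        self.leaves.append(leaf)

    def __len__(self) -> int:
        return len(self.leaves)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for leaf in self.leaves:
            mm = None
            if leaf.dpi is not None and leaf.scale_factor is not None:
                mm = MM_PER_INCH / (leaf.dpi * leaf.scale_factor)
            rows.append(
                {
                    "leaf_id": leaf.leaf_id,
                    "unit": "leaf",
                    "area_px2": leaf.area,
                    "perimeter_px": leaf.perimeter,
                    "rachis_length_px": leaf.rachis_length,
                    "rachis_node_count": leaf.rachis_node_count,
                    "petiole_length_px": leaf.petiole_length,
                    "n_leaflets": leaf.n_leaflets,
                    "area_mm2": leaf.area * mm * mm if mm else np.nan,
                    "perimeter_mm": leaf.perimeter * mm if mm else np.nan,
                    "dpi": leaf.dpi,
                    "scale_factor": leaf.scale_factor,
                    "source": leaf.source,
                }
            )
            for fl in leaf.leaflets:
                rows.append(
                    {
                        "leaf_id": leaf.leaf_id,
                        "unit": "leaflet",
                        "rank": fl.rank,
                        "side": fl.side,
                        "area_px2": fl.area,
                        "perimeter_px": fl.perimeter,
                        "major_axis_px": fl.major_axis,
                        "minor_axis_px": fl.minor_axis,
                        "eccentricity": fl.eccentricity,
                        "equivalent_diameter_px": fl.equivalent_diameter,
                        "petiolule_length_px": fl.petiolule_length,
                        "petiolule_node_count": fl.petiolule_node_count,
                        "base_to_branching_px": fl.base_to_branching,
                        "inter_rachis_px": fl.inter_rachis,
                        "area_mm2": fl.area * mm * mm if mm else np.nan,
                        "perimeter_mm": fl.perimeter * mm if mm else np.nan,
                        "dpi": leaf.dpi,
                        "scale_factor": leaf.scale_factor,
                        "source": leaf.source,
                    }
                )
        df = pd.DataFrame(rows)
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        return df[self.COLUMNS]


def write_feature_table(table: FeatureTable | pd.DataFrame, path) -> None:
    """Write the long-format CSV (stable column order, NaN → empty)."""
    df = table.to_frame() if isinstance(table, FeatureTable) else table
    if len(df) == 0:
        raise ValueError("feature table is empty")
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    return pd.read_csv(path, dtype={"leaf_id": str, "side": str, "source": str})
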