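"""Population-level summaries: metaleaf overlays and merged-feature PCA.

Each leaf's marker points (leaflet centers, cut nodes, branching nodes,
base and top point) are mapped into a common frame by the similarity
transform that sends the base point to (0, 0) and the top point to
(0, 1).  Two points fix exactly the four degrees of freedom of a
translation + rotation + uniform scale, so this is the unique such map
(a general affine map would be under-determined by two points).
Pooling the normalized markers of every leaf of a group produces the
"metaleaf", an overlay summarizing the group's morphological variety;
per-class centroids are the arithmetic means of the pooled points.

For a single low-dimensional leaf space, whole-leaf features are merged
with the features of the first few leaflet ranks (both sides), each
column z-scored — the features mix units (px, px², dimensionless), so
unscaled PCA would be dominated by areas — and passed to a principal
component analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateAxisError

log = logging.getLogger(__name__)

__all__ = [
    "MarkerPointSet",
    "Metaleaf",
    "MARKER_CLASSES",
    "normalize_leaf",
    "build_metaleaf",
    "plot_metaleaf",
    "merged_feature_pca",
    "PCAResult",
]

#: marker classes pooled into the metaleaf
MARKER_CLASSES = ("leaflet_center", "cut", "branching", "base", "top")


@dataclass
class MarkerPointSet:
    """One leaf's marker points in the normalized (x, y) frame."""

    points: dict[str, np.ndarray]  # class -> (N, 2) array
    leaf_id: str = "leaf"

    def __getitem__(self, cls: str) -> np.ndarray:
        return self.points.get(cls, np.empty((0, 2)))


def normalize_leaf(
    markers: dict[str, np.ndarray],
    base: tuple[float, float],
    top: tuple[float, float],
    leaf_id: str = "leaf",
) -> MarkerPointSet:
    """Similarity-transform all marker points so base→(0,0), top→(0,1).

    ``markers`` maps class names to (N, 2) arrays of (x, y) points in
    any common Cartesian frame; ``base`` and ``top`` are in the same
    frame.  Already-normalized input is a fixed point of this map.
    """
    zb = complex(base[0], base[1])
    zt = complex(top[0], top[1])
    denom = zt - zb
    if abs(denom) < 1e-12:
        raise DegenerateAxisError("base and top point coincide")
    out: dict[str, np.ndarray] = {}
    for cls, pts in markers.items():
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        z = pts[:, 0] + 1j * pts[:, 1]
        w = 1j * (z - zb) / denom  # multiply by i: top lands on (0, 1)
        out[cls] = np.stack([w.real, w.imag], axis=1)
    return MarkerPointSet(points=out, leaf_id=leaf_id)


@dataclass
class Metaleaf:
    """Pooled normalized markers of a group plus per-class centroids."""

    pooled: dict[str, np.ndarray]
    centroids: dict[str, np.ndarray]
    n_leaves: int = 0


def build_metaleaf(leaves: list[MarkerPointSet]) -> Metaleaf:
    """Pool marker points by class over all leaves and compute the
    per-class mean points."""
    if not leaves:
        raise ValueError("metaleaf needs at least one leaf")
    pooled: dict[str, list[np.ndarray]] = {}
    for leaf in leaves:
        for cls, pts in leaf.points.items():
            if len(pts):
                pooled.setdefault(cls, []).append(np.asarray(pts, dtype=float))
    pooled_arr = {cls: np.vstack(v) for cls, v in pooled.items()}
    centroids = {cls: v.mean(axis=0) for cls, v in pooled_arr.items()}
    return Metaleaf(pooled=pooled_arr, centroids=centroids, n_leaves=len(leaves))


_CLASS_COLORS = {
    "leaflet_center": "magenta",
    "cut": "tab:blue",
    "branching": "tab:green",
    "base": "gold",
    "top": "gold",
}


def plot_metaleaf(metaleaf: Metaleaf, ax=None, title: str | None = None):
    """Scatter overlay of the pooled markers; bordered markers are the
    per-class centroids."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    for cls, pts in metaleaf.pooled.items():
        color = _CLASS_COLORS.get(cls, "gray")
        ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.45, color=color, label=cls)
        cen = metaleaf.centroids[cls]
        ax.scatter([cen[0]], [cen[1]], s=70, color=color, edgecolors="black",
                   linewidths=1.2, zorder=5)
    ax.axhline(0, lw=0.4, color="0.7")
    ax.axvline(0, lw=0.4, color="0.7")
    ax.set_aspect("equal")
    ax.set_xlabel("x (leaf axis units)")
    ax.set_ylabel("y (leaf axis units)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="best")
    return ax


@dataclass
class PCAResult:
    scores: pd.DataFrame  # one row per leaf, columns PC1..PCk
    loadings: pd.DataFrame  # one row per feature column
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)
    excluded_leaves: list[str] = field(default_factory=list)


# whole-leaf and per-leaflet columns that enter the merged vector
_LEAF_COLS = ["area_px2", "perimeter_px", "rachis_length_px", "petiole_length_px"]
_LEAFLET_COLS = [
    "area_px2",
    "perimeter_px",
    "major_axis_px",
    "minor_axis_px",
    "eccentricity",
    "petiolule_length_px",
]


def merged_feature_pca(
    table: pd.DataFrame,
    n_leaflets: int = 3,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of merged whole-leaf + first-``n_leaflets``-rank features.

    ``table`` is the long-format feature table (one row per leaf/unit).
    Each leaf contributes its whole-leaf features plus the features of
    leaflet ranks 1..n_leaflets on both sides, in a fixed order; leaves
    lacking any of those leaflets are excluded (logged).  Columns are
    z-scored; constant columns are dropped with a warning.  Loadings
    follow the sign convention that each component's largest-magnitude
    entry is positive.
    """
    vectors: dict[str, dict[str, float]] = {}
    excluded: list[str] = []
    for leaf_id, sub in table.groupby("leaf_id", sort=True):
        whole = sub[sub["unit"] == "leaf"]
        leaflets = sub[sub["unit"] == "leaflet"]
        vec: dict[str, float] = {}
        for col in _LEAF_COLS:
            vec[f"leaf_{col}"] = float(whole.iloc[0][col]) if len(whole) else np.nan
        ok = True
        for rank in range(1, n_leaflets + 1):
            for side in ("left", "right"):
                row = leaflets[(leaflets["rank"] == rank) & (leaflets["side"] == side)]
                if len(row) == 0:
                    ok = False
                    break
                for col in _LEAFLET_COLS:
                    vec[f"r{rank}_{side}_{col}"] = float(row.iloc[0][col])
            if not ok:
                break
        if ok:
            vectors[str(leaf_id)] = vec
        else:
            excluded.append(str(leaf_id))
    if excluded:
        log.info("merged_feature_pca: excluded %d leaves with < %d leaflet ranks",
                 len(excluded), n_leaflets)
    if len(vectors) < 3:
        raise ValueError("merged-feature PCA needs at least 3 complete leaves")

    df = pd.DataFrame.from_dict(vectors, orient="index")
    dropped = [c for c in df.columns if df[c].std(ddof=0) <= 1e-12 or df[c].isna().any()]
    if dropped:
        log.warning("merged_feature_pca: dropping constant/NaN columns %s", dropped)
    df = df.drop(columns=dropped)
    # ddof=1 so each retained column has unit sample variance and the
    # component variances sum exactly to the number of columns
    z = (df - df.mean()) / df.std(ddof=1)

    k = n_components or min(z.shape)
    pca = PCA(n_components=min(k, min(z.shape)))
    scores = pca.fit_transform(z.values)
    comps = pca.components_
    # sign convention: largest-magnitude loading entry positive
    for j in range(comps.shape[0]):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] *= -1
            scores[:, j] *= -1
    pc_names = [f"PC{j + 1}" for j in range(comps.shape[0])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.index, columns=pc_names),
        loadings=pd.DataFrame(comps.T, index=df.columns, columns=pc_names),
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_columns=dropped,
        excluded_leaves=excluded,
    )
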