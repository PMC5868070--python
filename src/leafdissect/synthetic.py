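"""Synthetic dissected-leaf rasterizer with exact ground truth.

Emulates a scanned compound leaf: a petiole rising into a rachis
(optionally curved), lateral leaflet pairs attached through petiolules,
and a terminal leaflet at the apex.  Leaflets are filled ellipses,
stems are stroked polylines — the ellipses are deliberately fatter than
the stems, which is the geometric property the distance-transform cut
algorithm exploits.  Every rasterized unit comes with its exact pixel
mask and geometric lengths, so the whole downstream pipeline is
testable without real scans.

Coordinate conventions
----------------------
Geometry is laid out in a Cartesian (x, y) frame with the leaf base at
the origin and y pointing up (toward the leaf apex); rasters use image
(row, col) indices with the origin at the top-left, so the petiole ends
at high row indices, matching the orientation of a scanned leaf.
Anti-aliasing is never applied: the ground-truth mask is exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely import affinity
from shapely.geometry import LineString, Point
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .errors import SyntheticSpecError

__all__ = [
    "SyntheticLeafSpec",
    "SyntheticLeafTruth",
    "generate_leaf",
    "add_fissure",
    "random_grid_spec",
    "write_leaf",
]


def _as_tuple(value, n, name) -> tuple:
    """Broadcast a scalar or length-n sequence to an n-tuple."""
    if np.isscalar(value):
        return (value,) * n
    value = tuple(value)
    if len(value) != n:
        raise SyntheticSpecError(
            f"{name}: expected a scalar or a sequence of length {n}, got {len(value)}"
        )
    return value


@dataclass(frozen=True)
class SyntheticLeafSpec:
    """Parameters of one synthetic dissected leaf.

    Lengths are in pixels of the output raster.  ``branch_angles`` are
    measured from the local rachis direction (0° would run along the
    rachis; 90° is perpendicular).  Defaults describe a mid-sized leaf
    at the working scale of a 600 dpi scan rescaled to 25%: petiolules
    of ~26 px, the mean petiolule length observed on real material at
    that scale.
    """

    petiole_length: float = 60.0
    n_lateral_pairs: int = 2
    rachis_segment_lengths: tuple[float, ...] | None = None
    petiolule_lengths: float | Sequence[float] = 26.0
    leaflet_semi_axes: tuple[float, float] | Sequence[tuple[float, float]] = (22.0, 13.0)
    branch_angles: float | Sequence[float] = 50.0
    stem_width: float = 4.0
    terminal_leaflet_semi_axes: tuple[float, float] = (26.0, 16.0)
    rachis_curvature: float = 0.0  # degrees of rachis bend per segment, signed
    background_color: tuple[int, int, int] = (245, 245, 240)
    foreground_color: tuple[int, int, int] = (52, 140, 66)
    noise_sd: float = 0.0
    margin: int = 12
    seed: int = 0

    # -- derived, validated views -------------------------------------
    def lateral_count(self) -> int:
        return 2 * self.n_lateral_pairs

    def petiolules(self) -> tuple[float, ...]:
        return _as_tuple(self.petiolule_lengths, self.n_lateral_pairs, "petiolule_lengths")

    def semi_axes(self) -> tuple[tuple[float, float], ...]:
        ax = self.leaflet_semi_axes
        if len(ax) == 2 and np.isscalar(ax[0]):
            ax = (tuple(ax),) * self.n_lateral_pairs
        else:
            ax = tuple(tuple(a) for a in ax)
        if len(ax) != self.n_lateral_pairs:
            raise SyntheticSpecError(
                "leaflet_semi_axes: need one (a, b) pair per lateral pair"
            )
        return ax

    def angles(self) -> tuple[float, ...]:
        return _as_tuple(self.branch_angles, self.n_lateral_pairs, "branch_angles")

    def validate(self) -> None:
        if self.n_lateral_pairs < 0:
            raise SyntheticSpecError("n_lateral_pairs: must be >= 0")
        if self.petiole_length <= 0:
            raise SyntheticSpecError("petiole_length: all lengths must be > 0")
        if self.stem_width <= 0:
            raise SyntheticSpecError("stem_width: all lengths must be > 0")
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise_sd: must be >= 0")
        half = self.stem_width / 2.0
        axes = list(self.semi_axes()) + [tuple(self.terminal_leaflet_semi_axes)]
        for a, b in axes:
            if not (a >= b > half):
                raise SyntheticSpecError(
                    "leaflet_semi_axes: require a >= b > stem_width/2 "
                    f"(got a={a}, b={b}, stem_width={self.stem_width})"
                )
        for p in self.petiolules():
            if p <= 0:
                raise SyntheticSpecError("petiolule_lengths: all lengths must be > 0")
        for ang in self.angles():
            if not (5.0 <= ang <= 120.0):
                raise SyntheticSpecError(
                    f"branch_angles: expected 5..120 degrees from the rachis, got {ang}"
                )
        if self.rachis_segment_lengths is not None:
            if len(self.rachis_segment_lengths) != max(self.n_lateral_pairs, 0) or any(
                s <= 0 for s in self.rachis_segment_lengths
            ):
                raise SyntheticSpecError(
                    "rachis_segment_lengths: need n_lateral_pairs positive spans "
                    "(between consecutive attachment joints, last span to the "
                    "terminal leaflet)"
                )


@dataclass
class SyntheticLeafTruth:
    """A rasterized leaf plus its exact ground truth.

    ``leaflet_masks`` are ordered laterals bottom-up, (left, right) per
    pair, terminal last; ``cut_positions`` and ``leaflet_info`` follow
    the same order.  ``unit_lengths`` holds the geometric (requested)
    lengths of every stem unit in pixels.
    """

    spec: SyntheticLeafSpec
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, noiseless ground truth
    leaflet_masks: list[np.ndarray]
    leaflet_info: list[dict]
    unit_lengths: dict[str, float]
    cut_positions: list[tuple[int, int]]
    branch_positions: list[tuple[int, int]]
    landmark_axis: tuple[tuple[int, int], tuple[int, int]]

    @property
    def stem_mask(self) -> np.ndarray:
        out = self.mask.copy()
        for m in self.leaflet_masks:
            out &= ~m
        return out

    @property
    def n_leaflets(self) -> int:
        return len(self.leaflet_masks)


def _rot(vec: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate a 2-vector counterclockwise (Cartesian, y up)."""
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


class _Layout:
    """Resolved Cartesian geometry of one leaf before rasterization."""

    def __init__(self, spec: SyntheticLeafSpec, segments: tuple[float, ...]):
        n = spec.n_lateral_pairs
        self.segments = segments
        d = np.array([0.0, 1.0])
        base = np.array([0.0, 0.0])
        self.base = base
        self.joints: list[np.ndarray] = []
        self.joint_dirs: list[np.ndarray] = []
        pos = base + spec.petiole_length * d
        for i in range(n):
            self.joints.append(pos.copy())
            self.joint_dirs.append(d.copy())
            d = _rot(d, spec.rachis_curvature)
            pos = pos + segments[i] * d
        self.attachment = pos
        self.terminal_dir = d
        a_t, b_t = spec.terminal_leaflet_semi_axes
        self.terminal_center = pos + a_t * d
        self.terminal_tip = pos + 2 * a_t * d
        # lateral leaflets: (pair, side) -> petiolule direction / center
        self.laterals: list[dict] = []
        pets, axes, angs = (spec.petiolules(), spec.semi_axes(), spec.angles()) if n else ((), (), ())
        for i in range(n):
            for side, sgn in (("left", +1.0), ("right", -1.0)):
                u = _rot(self.joint_dirs[i], sgn * angs[i])
                a, b = axes[i]
                self.laterals.append(
                    {
                        "pair": i,
                        "side": side,
                        "u": u,
                        "a": a,
                        "b": b,
                        "petiolule": pets[i],
                        "joint": self.joints[i],
                        "center": self.joints[i] + (pets[i] + a) * u,
                        "cut": self.joints[i] + pets[i] * u,
                    }
                )

    def ellipse_polygon(self, center, a, b, u):
        ell = Point(center[0], center[1]).buffer(1.0, quad_segs=64)
        ell = affinity.scale(ell, a, b, origin=(center[0], center[1]))
        ang = math.degrees(math.atan2(u[1], u[0]))
        return affinity.rotate(ell, ang, origin=(center[0], center[1]))


def _layout_overlaps(layout: _Layout, spec: SyntheticLeafSpec) -> bool:
    """True if leaflets touch each other or a foreign stem segment."""
    polys = [
        layout.ellipse_polygon(l["center"], l["a"], l["b"], l["u"])
        for l in layout.laterals
    ]
    a_t, b_t = spec.terminal_leaflet_semi_axes
    polys.append(
        layout.ellipse_polygon(layout.terminal_center, a_t, b_t, layout.terminal_dir)
    )
    clearance = 2.0
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].distance(polys[j]) < clearance:
                return True
    # rachis polyline (base -> attachment); laterals must stay clear of it
    pts = [tuple(layout.base)] + [tuple(j) for j in layout.joints] + [tuple(layout.attachment)]
    rachis = LineString(pts)
    for poly in polys[:-1]:
        if poly.distance(rachis) < spec.stem_width / 2.0 + 1.5:
            return True
    return False


def _default_segments(spec: SyntheticLeafSpec) -> tuple[float, ...]:
    n = spec.n_lateral_pairs
    if n == 0:
        return ()
    axes = spec.semi_axes()
    a_t = spec.terminal_leaflet_semi_axes[0]
    segs = []
    for i in range(n):
        a_here = axes[i][0]
        a_next = axes[i + 1][0] if i + 1 < n else a_t
        segs.append(max(32.0, math.ceil(1.8 * max(a_here, a_next)) + spec.stem_width))
    # last span runs up to the terminal leaflet; give it extra clearance
    segs[-1] = max(40.0, segs[-1] * 1.2)
    return tuple(segs)


def _resolve_layout(spec: SyntheticLeafSpec) -> _Layout:
    user_given = spec.rachis_segment_lengths is not None
    segments = (
        tuple(float(s) for s in spec.rachis_segment_lengths)
        if user_given
        else _default_segments(spec)
    )
    layout = _Layout(spec, segments)
    if spec.n_lateral_pairs == 0:
        return layout
    for _ in range(25):
        if not _layout_overlaps(layout, spec):
            return layout
        if user_given:
            raise SyntheticSpecError(
                "rachis_segment_lengths: requested geometry makes leaflet masks "
                "overlap (leaflet_masks must be pairwise disjoint)"
            )
        segments = tuple(s * 1.15 for s in segments)
        layout = _Layout(spec, segments)
    raise SyntheticSpecError(
        "could not auto-space rachis segments to keep leaflet masks disjoint"
    )


def _canvas_transform(layout: _Layout, spec: SyntheticLeafSpec):
    """Bounds of all geometry -> (shape, xy->rc mapping)."""
    pts = [layout.base, layout.attachment, layout.terminal_tip] + [
        np.asarray(j) for j in layout.joints
    ]
    reach = []
    for l in layout.laterals:
        reach.append(l["center"] + l["a"] * l["u"])
        reach.append(l["center"] - l["a"] * l["u"])
        v = _rot(l["u"], 90.0)
        reach.append(l["center"] + l["b"] * v)
        reach.append(l["center"] - l["b"] * v)
    a_t, b_t = spec.terminal_leaflet_semi_axes
    v = _rot(layout.terminal_dir, 90.0)
    reach += [layout.terminal_center + b_t * v, layout.terminal_center - b_t * v]
    allpts = np.array([p for p in pts] + reach)
    m = spec.margin + spec.stem_width
    xmin, ymin = allpts.min(axis=0) - m
    xmax, ymax = allpts.max(axis=0) + m
    H = int(math.ceil(ymax - ymin)) + 1
    W = int(math.ceil(xmax - xmin)) + 1

    def to_rc(p):
        return (ymax - p[1], p[0] - xmin)

    return (H, W), to_rc


def _stroke(canvas: np.ndarray, p1, p2, width: float, to_rc) -> None:
    """Rasterize a flat-capped thick segment onto a boolean canvas."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    d = p2 - p1
    n = np.linalg.norm(d)
    if n < 1e-9:
        return
    d = d / n
    perp = np.array([-d[1], d[0]]) * (width / 2.0)
    corners = [p1 + perp, p2 + perp, p2 - perp, p1 - perp]
    rr_cc = np.array([to_rc(c) for c in corners])
    rr, cc = draw_polygon(rr_cc[:, 0], rr_cc[:, 1], shape=canvas.shape)
    canvas[rr, cc] = True


def _joint_disk(canvas: np.ndarray, p, width: float, to_rc) -> None:
    r, c = to_rc(p)
    rr, cc = draw_disk((r, c), max(width / 2.0, 1.0), shape=canvas.shape)
    canvas[rr, cc] = True


def _ellipse_mask(shape, center, a, b, u, to_rc) -> np.ndarray:
    """Exact (inclusive) raster of a rotated filled ellipse."""
    H, W = shape
    rc = np.array(to_rc(center))
    ext = max(a, b) + 2
    r0, r1 = max(int(rc[0] - ext), 0), min(int(rc[0] + ext) + 1, H)
    c0, c1 = max(int(rc[1] - ext), 0), min(int(rc[1] + ext) + 1, W)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    # back to Cartesian offsets: x grows with col, y shrinks with row
    dx = cols - rc[1]
    dy = rc[0] - rows
    pa = dx * u[0] + dy * u[1]
    v = _rot(u, 90.0)
    pb = dx * v[0] + dy * v[1]
    inside = (pa / a) ** 2 + (pb / b) ** 2 <= 1.0
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = inside
    return out


def generate_leaf(spec: SyntheticLeafSpec) -> SyntheticLeafTruth:
    """Rasterize one dissected leaf and return it with exact ground truth.

    Deterministic for a fixed ``spec.seed``; the only stochastic step is
    the additive intensity noise.
    """
    spec.validate()
    layout = _resolve_layout(spec)
    shape, to_rc = _canvas_transform(layout, spec)

    stems = np.zeros(shape, dtype=bool)
    # petiole + rachis polyline
    axis_pts = [layout.base] + layout.joints + [layout.attachment]
    for p1, p2 in zip(axis_pts[:-1], axis_pts[1:]):
        _stroke(stems, p1, p2, spec.stem_width, to_rc)
    for j in layout.joints:
        _joint_disk(stems, j, spec.stem_width, to_rc)
    # overdraw into the terminal ellipse so no gap can open at the apex
    _stroke(stems, layout.attachment, layout.terminal_center, spec.stem_width, to_rc)
    # petiolules, overdrawn to the leaflet center for the same reason
    for l in layout.laterals:
        _stroke(stems, l["joint"], l["center"], spec.stem_width, to_rc)

    leaflet_masks: list[np.ndarray] = []
    leaflet_info: list[dict] = []
    cut_positions: list[tuple[int, int]] = []
    for l in layout.laterals:
        m = _ellipse_mask(shape, l["center"], l["a"], l["b"], l["u"], to_rc)
        leaflet_masks.append(m)
        rc = to_rc(l["cut"])
        cut_positions.append((int(round(rc[0])), int(round(rc[1]))))
        crc = to_rc(l["center"])
        leaflet_info.append(
            {
                "side": l["side"],
                "pair": l["pair"],
                "center": (int(round(crc[0])), int(round(crc[1]))),
                "semi_axes": (l["a"], l["b"]),
            }
        )
    a_t, b_t = spec.terminal_leaflet_semi_axes
    term_mask = _ellipse_mask(
        shape, layout.terminal_center, a_t, b_t, layout.terminal_dir, to_rc
    )
    leaflet_masks.append(term_mask)
    rc = to_rc(layout.attachment)
    cut_positions.append((int(round(rc[0])), int(round(rc[1]))))
    crc = to_rc(layout.terminal_center)
    leaflet_info.append(
        {
            "side": "terminal",
            "pair": None,
            "center": (int(round(crc[0])), int(round(crc[1]))),
            "semi_axes": (a_t, b_t),
        }
    )

    union = np.zeros(shape, dtype=bool)
    for i, m in enumerate(leaflet_masks):
        if (union & m).any():
            raise SyntheticSpecError(
                "leaflet_masks: rasterized leaflets overlap (must be pairwise disjoint)"
            )
        union |= m
    stems &= ~union
    mask = stems | union

    img = np.empty(shape + (3,), dtype=np.uint8)
    img[:] = np.asarray(spec.background_color, dtype=np.uint8)
    img[mask] = np.asarray(spec.foreground_color, dtype=np.uint8)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = img.astype(np.float64) + rng.normal(0.0, spec.noise_sd, img.shape)
        img = np.clip(noisy, 0, 255).astype(np.uint8)

    n = spec.n_lateral_pairs
    unit_lengths: dict[str, float] = {
        "petiole": float(spec.petiole_length),
        "rachis": float(spec.petiole_length + sum(layout.segments)),
    }
    pets = spec.petiolules() if n else ()
    for i in range(n):
        unit_lengths[f"petiolule_{i}"] = float(pets[i])
    if n:
        unit_lengths["petiolule_terminal"] = float(layout.segments[-1])
        for i in range(n - 1):
            unit_lengths[f"inter_rachis_{i}"] = float(layout.segments[i])
    else:
        unit_lengths["petiolule_terminal"] = float(spec.petiole_length)

    branch_positions = []
    for j in layout.joints:
        rc = to_rc(j)
        branch_positions.append((int(round(rc[0])), int(round(rc[1]))))
    base_rc = to_rc(layout.base)
    tip_rc = to_rc(layout.terminal_tip)
    axis = (
        (int(round(base_rc[0])), int(round(base_rc[1]))),
        (int(round(tip_rc[0])), int(round(tip_rc[1]))),
    )

    return SyntheticLeafTruth(
        spec=spec,
        image=img,
        mask=mask,
        leaflet_masks=leaflet_masks,
        leaflet_info=leaflet_info,
        unit_lengths=unit_lengths,
        cut_positions=cut_positions,
        branch_positions=branch_positions,
        landmark_axis=axis,
    )


def add_fissure(
    truth: SyntheticLeafTruth,
    leaflet_index: int = -1,
    depth_frac: float = 0.45,
    width_px: float = 3.0,
) -> SyntheticLeafTruth:
    """Carve a thin background wedge into one leaflet.

    Emulates the fixation fissures seen in real scans: the leaflet
    becomes non-convex but stays a single connected unit.  Returns a new
    truth object; the leaflet's mask shrinks by the wedge.
    """
    info = truth.leaflet_info[leaflet_index]
    lm = truth.leaflet_masks[leaflet_index]
    a, b = info["semi_axes"]
    center = np.array(info["center"], dtype=float)  # (row, col)
    # wedge runs from the leaflet tip (farthest mask pixel from center
    # along the major axis) toward the center
    rows, cols = np.nonzero(lm)
    pts = np.stack([rows, cols], axis=1).astype(float)
    d2 = ((pts - center) ** 2).sum(axis=1)
    tip = pts[int(np.argmax(d2))]
    u = (center - tip) / np.linalg.norm(center - tip)
    perp = np.array([-u[1], u[0]])
    depth = depth_frac * a
    apex = tip + depth * u
    c1 = tip + perp * (width_px / 2.0)
    c2 = tip - perp * (width_px / 2.0)
    rr, cc = draw_polygon(
        [c1[0], c2[0], apex[0]], [c1[1], c2[1], apex[1]], shape=lm.shape
    )
    wedge = np.zeros_like(lm)
    wedge[rr, cc] = True
    wedge &= lm

    image = truth.image.copy()
    image[wedge] = np.asarray(truth.spec.background_color, dtype=np.uint8)
    mask = truth.mask & ~wedge
    masks = [m.copy() for m in truth.leaflet_masks]
    masks[leaflet_index] = lm & ~wedge
    return SyntheticLeafTruth(
        spec=truth.spec,
        image=image,
        mask=mask,
        leaflet_masks=masks,
        leaflet_info=truth.leaflet_info,
        unit_lengths=truth.unit_lengths,
        cut_positions=truth.cut_positions,
        branch_positions=truth.branch_positions,
        landmark_axis=truth.landmark_axis,
    )


def random_grid_spec(rng: np.random.Generator, *, noise_sd: float = 4.0) -> SyntheticLeafSpec:
    """Draw one leaf spec from the evaluation parameter box.

    Lateral pairs 1–7, leaflet semi-major axis 8–40 px (aspect fixed at
    b = 0.6 a), stem width 2–6 px; branch angle 50° and petiolules of
    26 px throughout (realistic for the working scan scale).
    """
    n_pairs = int(rng.integers(1, 8))
    a = float(rng.uniform(8.0, 40.0))
    b = max(0.6 * a, 0.51 * 6.0 + 0.1)
    w = float(rng.integers(2, 7))
    b = max(b, w / 2.0 + 1.0)
    a = max(a, b)
    return SyntheticLeafSpec(
        petiole_length=float(rng.uniform(50.0, 80.0)),
        n_lateral_pairs=n_pairs,
        leaflet_semi_axes=(a, b),
        terminal_leaflet_semi_axes=(1.2 * a, 1.2 * b),
        stem_width=w,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_leaf(truth: SyntheticLeafTruth, png_path, json_path=None) -> None:
    """Write the leaf image as PNG plus a JSON ground-truth sidecar."""
    from PIL import Image

    png_path = Path(png_path)
    Image.fromarray(truth.image).save(png_path)
    if json_path is None:
        json_path = png_path.with_suffix(".json")
    sidecar = {
        "n_leaflets": truth.n_leaflets,
        "unit_lengths": truth.unit_lengths,
        "cut_positions": [list(p) for p in truth.cut_positions],
        "branch_positions": [list(p) for p in truth.branch_positions],
        "landmark_axis": [list(p) for p in truth.landmark_axis],
        "leaflets": [
            {
                "side": i["side"],
                "pair": i["pair"],
                "center": list(i["center"]),
                "semi_axes": list(i["semi_axes"]),
            }
            for i in truth.leaflet_info
        ],
        "spec": {
            "petiole_length": truth.spec.petiole_length,
            "n_lateral_pairs": truth.spec.n_lateral_pairs,
            "stem_width": truth.spec.stem_width,
            "noise_sd": truth.spec.noise_sd,
            "seed": truth.spec.seed,
        },
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=1))
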