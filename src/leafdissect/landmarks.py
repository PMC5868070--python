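"""Terminal-leaflet landmarks and export for morphometrics software.

Eight landmarks are constructed on the terminal-leaflet outline:

1. the *top point* — the far intersection of the outline with the line
   from the leaf base node through the terminal cut node;
2. the *basal point* — the intersection of that axis nearest the base;
3-4. the endpoints of the longest chord perpendicular to the axis
   (the width chord);
5-8. the outline intersections of the two lines through the width-chord
   midpoint at ±45° to the axis.

The set is emitted in clockwise order starting from the top point
(clockwise as seen in the upright, y-up view of the leaf).  On a
circular leaflet the construction degenerates to eight points spaced
45° apart.  Landmarks and resampled outlines are written in the plain
text formats consumed by downstream geometric-morphometrics tools
(TPS landmark files; x,y coordinate blocks for outline analysis).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point

from .errors import LandmarkError

log = logging.getLogger(__name__)

__all__ = [
    "OutlineTrace",
    "LandmarkSet",
    "outline_trace",
    "terminal_top_point",
    "place_landmarks",
    "export_tps",
    "read_tps",
    "export_outline",
    "resample_closed",
    "rotate_to_start",
]


@dataclass
class OutlineTrace:
    """Closed outline of a leaflet as an ordered (row, col) chain.

    The chain is closed (first point == last point); sub-pixel vertices
    are allowed (the trace follows the 0.5-level contour of the mask).
    """

    points: np.ndarray  # (N, 2) float, closed

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if len(pts) < 4 or not np.allclose(pts[0], pts[-1]):
            raise ValueError("outline must be a closed chain (first == last point)")
        self.points = pts

    @property
    def open_points(self) -> np.ndarray:
        return self.points[:-1]

    def as_linestring(self) -> LineString:
        return LineString([(p[1], -p[0]) for p in self.points])  # (x, y up)

    def chain_length(self) -> float:
        return float(np.hypot(*np.diff(self.points, axis=0).T).sum())


def outline_trace(mask: np.ndarray) -> OutlineTrace:
    """Trace the (longest) closed outline of a boolean mask."""
    from skimage.measure import find_contours

    contours = find_contours(np.asarray(mask, dtype=float), 0.5)
    if not contours:
        raise LandmarkError("mask has no outline contour")
    pts = max(contours, key=len)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[:1]])
    return OutlineTrace(points=pts)


def _to_xy(p) -> np.ndarray:
    """(row, col) -> upright Cartesian (x, y up)."""
    return np.array([p[1], -p[0]], dtype=float)


def _to_rc(p) -> np.ndarray:
    return np.array([-p[1], p[0]], dtype=float)


def _line_through(point_xy, direction_xy, half_len) -> LineString:
    d = np.asarray(direction_xy, dtype=float)
    d = d / np.linalg.norm(d)
    p = np.asarray(point_xy, dtype=float)
    return LineString([tuple(p - half_len * d), tuple(p + half_len * d)])


def _intersection_points(outline_ls: LineString, line: LineString) -> list[np.ndarray]:
    inter = outline_ls.intersection(line)
    if inter.is_empty:
        return []
    if isinstance(inter, Point):
        return [np.array([inter.x, inter.y])]
    if isinstance(inter, MultiPoint):
        return [np.array([g.x, g.y]) for g in inter.geoms]
    # collinear overlap or mixed collection: take representative vertices
    pts = []
    for g in getattr(inter, "geoms", [inter]):
        if isinstance(g, Point):
            pts.append(np.array([g.x, g.y]))
        else:
            pts.extend(np.asarray(g.coords))
    return [np.asarray(p) for p in pts]


def terminal_top_point(
    terminal_outline: OutlineTrace,
    base: tuple[float, float],
    terminal_cut: tuple[float, float],
) -> tuple[float, float]:
    """Apex of the terminal leaflet: the intersection of the
    base→terminal-cut line with the leaflet outline farthest from the
    base.  Returns a (row, col) point on the outline."""
    b = _to_xy(base)
    c = _to_xy(terminal_cut)
    if np.allclose(b, c):
        raise LandmarkError("base and terminal cut node coincide")
    ls = terminal_outline.as_linestring()
    diam = max(np.ptp(terminal_outline.points[:, 0]), np.ptp(terminal_outline.points[:, 1]))
    span = np.linalg.norm(c - b) + 4 * diam + 10
    line = _line_through(b, c - b, span)
    pts = _intersection_points(ls, line)
    if not pts:
        raise LandmarkError("leaf axis does not intersect the terminal outline")
    far = max(pts, key=lambda p: np.linalg.norm(p - b))
    rc = _to_rc(far)
    return (float(rc[0]), float(rc[1]))


@dataclass
class LandmarkSet:
    """8 ordered landmarks on the terminal leaflet outline.

    ``points`` are (row, col); point 1 is the top point and the rest
    follow clockwise (in the upright view).  ``image_height`` lets the
    TPS export flip rows into Cartesian y coordinates.
    """

    points: np.ndarray  # (8, 2)
    axis: tuple[tuple[float, float], tuple[float, float]]  # (base, top)
    leaf_id: str = "leaf"
    image_height: int | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (8, 2):
            raise ValueError("a LandmarkSet holds exactly 8 (row, col) points")


def place_landmarks(
    terminal_outline: OutlineTrace,
    base: tuple[float, float],
    top: tuple[float, float],
    leaf_id: str = "leaf",
    image_height: int | None = None,
    n_chord_samples: int = 600,
) -> LandmarkSet:
    """Construct the 8-landmark set from the axis and the outline.

    The width chord is found by scanning ``n_chord_samples`` axis
    positions for the longest perpendicular chord; the ±45° lines are
    anchored at the width-chord midpoint.
    """
    b = _to_xy(base)
    t = _to_xy(top)
    axis_vec = t - b
    axis_len = np.linalg.norm(axis_vec)
    if axis_len < 1e-9:
        raise LandmarkError("degenerate axis: base equals top")
    u = axis_vec / axis_len
    v = np.array([-u[1], u[0]])  # perpendicular

    ls = terminal_outline.as_linestring()
    xy = np.stack([terminal_outline.points[:, 1], -terminal_outline.points[:, 0]], axis=1)
    proj = (xy - b) @ u
    lo, hi = proj.min(), proj.max()
    span = float(np.hypot(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]))) + 10

    def chord_at(s):
        anchor = b + s * u
        pts = _intersection_points(ls, _line_through(anchor, v, span))
        if len(pts) < 2:
            return None
        tproj = [(p - anchor) @ v for p in pts]
        i_min, i_max = int(np.argmin(tproj)), int(np.argmax(tproj))
        return tproj[i_max] - tproj[i_min], pts[i_min], pts[i_max]

    samples = []
    for s in np.linspace(lo + 1e-6, hi - 1e-6, n_chord_samples):
        res = chord_at(s)
        if res is not None:
            samples.append((s, res[0]))
    if not samples:
        raise LandmarkError("no perpendicular chord intersects the outline twice")
    # rasterized outlines have a flat chord-length profile near the
    # maximum; the center of the near-maximal band is the stable choice
    lengths = np.array([c for _, c in samples])
    positions = np.array([s for s, _ in samples])
    band = lengths >= lengths.max() - 0.75
    s_star = float(positions[band].mean())
    res = chord_at(s_star)
    if res is None:
        res = chord_at(positions[int(np.argmax(lengths))])
    chord_len, w1, w2 = res
    mid = (np.asarray(w1) + np.asarray(w2)) / 2.0

    diag_pts = []
    for ang in (45.0, -45.0):
        ca, sa = math.cos(math.radians(ang)), math.sin(math.radians(ang))
        d = np.array([ca * u[0] - sa * u[1], sa * u[0] + ca * u[1]])
        pts = _intersection_points(ls, _line_through(mid, d, span))
        if len(pts) < 2:
            raise LandmarkError("45-degree construction line misses the outline")
        tproj = [(p - mid) @ d for p in pts]
        diag_pts.append(pts[int(np.argmax(tproj))])
        diag_pts.append(pts[int(np.argmin(tproj))])

    # basal point: axis intersection nearest the base
    axis_pts = _intersection_points(ls, _line_through(b, u, axis_len + span))
    if not axis_pts:
        raise LandmarkError("axis does not intersect the outline")
    basal = min(axis_pts, key=lambda p: np.linalg.norm(p - b))
    top_xy = _to_xy(top)

    pts = [top_xy, np.asarray(w1), np.asarray(w2), basal] + [np.asarray(p) for p in diag_pts]
    centroid = np.mean(pts, axis=0)
    ang0 = math.atan2(top_xy[1] - centroid[1], top_xy[0] - centroid[0])

    def cw_key(p):
        a = math.atan2(p[1] - centroid[1], p[0] - centroid[0])
        return (ang0 - a) % (2 * math.pi)  # clockwise from the top point

    ordered = sorted(pts, key=cw_key)
    rc = np.array([_to_rc(p) for p in ordered])
    return LandmarkSet(
        points=rc,
        axis=(tuple(map(float, base)), tuple(map(float, top))),
        leaf_id=leaf_id,
        image_height=image_height,
    )


def export_tps(landmark_sets: list[LandmarkSet], path) -> None:
    """Write landmark sets as a TPS file.

    One record per specimen: an ``LM=8`` line, eight ``x y`` coordinate
    lines (y flipped to the Cartesian convention using the image
    height), and an ``ID=<leaf id>`` line.
    """
    for s in landmark_sets:
        if s.points.shape != (8, 2):
            raise ValueError("all landmark sets must have exactly 8 points")
    lines = []
    for s in landmark_sets:
        h = s.image_height if s.image_height is not None else 0
        lines.append(f"LM={len(s.points)}")
        for r, c in s.points:
            y = (h - r) if s.image_height is not None else -r
            lines.append(f"{c:.6f} {y:.6f}")
        lines.append(f"ID={s.leaf_id}")
    if not landmark_sets:
        log.warning("exporting an empty TPS file")
    text = "\n".join(lines)
    with open(path, "w") as fh:
        fh.write(text + ("\n" if text else ""))


def read_tps(path) -> list[tuple[str, np.ndarray]]:
    """Parse a TPS file back into (id, (n, 2) x/y array) records."""
    records = []
    coords: list[list[float]] = []
    leaf_id = None
    n_expected = 0
    for raw in open(path):
        line = raw.strip()
        if not line:
            continue
        if line.upper().startswith("LM="):
            coords = []
            n_expected = int(line.split("=", 1)[1])
            leaf_id = None
        elif line.upper().startswith("ID="):
            leaf_id = line.split("=", 1)[1]
            if len(coords) != n_expected:
                raise ValueError("TPS record has wrong number of coordinates")
            records.append((leaf_id, np.asarray(coords, dtype=float)))
        else:
            x, y = line.split()
            coords.append([float(x), float(y)])
    return records


def rotate_to_start(trace: OutlineTrace, start: tuple[float, float]) -> OutlineTrace:
    """Re-close the outline chain so it starts at the vertex nearest
    ``start`` (row, col) — typically the top point."""
    pts = trace.open_points
    i = int(np.argmin(((pts - np.asarray(start, dtype=float)) ** 2).sum(axis=1)))
    rolled = np.roll(pts, -i, axis=0)
    return OutlineTrace(points=np.vstack([rolled, rolled[:1]]))


def resample_closed(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed chain at n equally spaced arc-length positions
    starting from the chain's first vertex (endpoint not duplicated)."""
    pts = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    out = np.empty((n_points, 2))
    out[:, 0] = np.interp(targets, arc, pts[:, 0])
    out[:, 1] = np.interp(targets, arc, pts[:, 1])
    return out


def export_outline(outlines: list[OutlineTrace], path, n_points: int = 100, ids=None) -> None:
    """Resample each closed outline to ``n_points`` arc-length-equal
    positions and write one ``x,y`` coordinate block per leaf.

    Block format: a header line ``ID=<leaf id>``, then ``n_points``
    comma-separated ``x,y`` lines (Cartesian, y up), blocks separated
    by a blank line.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    ids = ids or [f"leaf{i}" for i in range(len(outlines))]
    blocks = []
    for oid, tr in zip(ids, outlines):
        res = resample_closed(tr.points, n_points)
        lines = [f"ID={oid}"]
        for r, c in res:
            lines.append(f"{c:.6f},{-r:.6f}")
        blocks.append("\n".join(lines))
    with open(path, "w") as fh:
        fh.write("\n\n".join(blocks) + ("\n" if blocks else ""))
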