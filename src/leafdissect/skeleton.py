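"""Distance transform, pruned skeleton, and the annotated skeleton graph.

The skeleton (medial axis) of the leaf mask is turned into a graph with
one node per skeleton pixel and one edge per 8-adjacent pixel pair;
each node carries the Euclidean distance-transform value at that pixel,
i.e. the radius of the largest inscribed circle centered there.  Nodes
of degree 1 are *extremal*, nodes of degree >= 3 are *junctions*; the
base node (lower end of the petiole) is the extremal node with the
maximal row index, assuming the scanning convention of petiole-down
orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import EmptyMaskError, PruningCollapseError, TopologyError

log = logging.getLogger(__name__)

__all__ = [
    "fork_pixels",
    "distance_transform",
    "skeletonize",
    "prune_skeleton",
    "build_graph",
    "find_base_node",
    "SkeletonGraph",
    "path_chain_length",
]

#: default minimum branch length (pixels) kept by pruning
DEFAULT_PRUNE_PX = 25

# 8-neighborhood offsets
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def distance_transform(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each foreground pixel to the
    nearest background pixel; 0 on background.

    The image border counts as adjacent to background so that a mask
    touching the frame still gets finite distances.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("distance transform of an empty mask")
    padded = np.pad(mask, 1, constant_values=False)
    d = ndimage.distance_transform_edt(padded)
    return d[1:-1, 1:-1]


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide skeleton of the mask (boolean raster).

    Connectivity of the input component is preserved; the specific
    thinning algorithm is a standard one — the contract is thinness,
    connectivity, and mediality, not the algorithm identity.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("skeleton of an empty mask")
    return _sk_skeletonize(mask)


def _neighbors(px, pixel_set):
    r, c = px
    for dr, dc in _OFFSETS:
        q = (r + dr, c + dc)
        if q in pixel_set:
            yield q


def _adjacency_components(points: set) -> int:
    """Number of 8-connected components within a small pixel set."""
    comps = 0
    seen: set = set()
    for q in points:
        if q in seen:
            continue
        comps += 1
        stack = [q]
        seen.add(q)
        while stack:
            x = stack.pop()
            for z in points:
                if z not in seen and max(abs(z[0] - x[0]), abs(z[1] - x[1])) <= 1:
                    seen.add(z)
                    stack.append(z)
    return comps


def fork_pixels(pixel_set: set) -> set:
    """Pixels belonging to genuine skeleton forks.

    Raw degree is unreliable on 8-connected skeletons: staircase
    corners form pixel triangles whose members look like degree-3
    junctions, while a real joint is often a small *cluster* of
    adjacent degree->=3 pixels none of which individually shows three
    separated neighbors.  A cluster of adjacent degree->=3 pixels is a
    genuine fork iff the skeleton branches leaving the cluster (the
    8-connected components of its external neighbors) number >= 3.
    Returns the union of all genuine-fork cluster pixels.
    """
    degree = {p: sum(1 for _ in _neighbors(p, pixel_set)) for p in pixel_set}
    junctions = {p for p, d in degree.items() if d >= 3}
    result: set = set()
    seen: set = set()
    for n in junctions:
        if n in seen:
            continue
        cluster = {n}
        stack = [n]
        seen.add(n)
        while stack:
            x = stack.pop()
            for q in _neighbors(x, pixel_set):
                if q in junctions and q not in seen:
                    seen.add(q)
                    cluster.add(q)
                    stack.append(q)
        external = set()
        for x in cluster:
            for q in _neighbors(x, pixel_set):
                if q not in cluster:
                    external.add(q)
        if _adjacency_components(external) >= 3:
            result |= cluster
    return result


def prune_skeleton(
    skeleton: np.ndarray,
    distance: np.ndarray | None = None,
    min_branch_len: int = DEFAULT_PRUNE_PX,
) -> np.ndarray:
    """Iteratively remove terminal branches shorter than ``min_branch_len``.

    A branch is the simple path from a degree-1 pixel to the nearest
    genuine fork (the fork itself is never removed).  Rounds repeat
    until no branch falls below the threshold, so stubs exposed by a
    previous round get pruned too.  Branch length is the pixel count
    along the path.  A skeleton that is a single junction-free path is
    never pruned away.

    When the distance map is supplied, a short branch is only treated
    as a spur if it is not *medially salient*: a noise spur points
    toward the boundary, so its distance values never rise above the
    fork's, whereas the short internal skeleton of a small blade climbs
    well above it and must survive even below the length threshold.
    """
    if min_branch_len < 0:
        raise ValueError("min_branch_len must be >= 0")
    skeleton = np.asarray(skeleton, dtype=bool)
    pixels = set(zip(*map(list, np.nonzero(skeleton))))
    if not pixels:
        raise EmptyMaskError("pruning an empty skeleton")
    if min_branch_len == 0:
        return skeleton.copy()

    while True:
        degree = {p: sum(1 for _ in _neighbors(p, pixels)) for p in pixels}
        endpoints = [p for p, d in degree.items() if d == 1]
        to_delete: set = set()
        forks = fork_pixels(pixels)
        for ep in endpoints:
            # walk from the tip until the first genuine fork; the branch
            # is everything before it
            branch: list = []
            visited = {ep}
            prev, cur = None, ep
            hit_junction = False
            while True:
                if cur in forks:
                    hit_junction = True
                    break
                branch.append(cur)
                nbrs = [q for q in _neighbors(cur, pixels)
                        if q != prev and q not in visited]
                if not nbrs:
                    break  # reached the far end of a junction-free path
                prev, cur = cur, nbrs[0]
                visited.add(cur)
            if hit_junction and len(branch) < min_branch_len:
                if distance is not None and len(branch):
                    d_branch = max(float(distance[p]) for p in branch)
                    if d_branch > float(distance[cur]) + 1.0:
                        continue  # medially salient: blade, not a spur
                to_delete.update(branch)
        if not to_delete:
            break
        if to_delete >= pixels:
            raise PruningCollapseError("pruning would delete the entire skeleton")
        pixels -= to_delete

    # deleting a branch can leave a redundant corner pixel of its old
    # fork cluster behind (a 1-px nub whose neighbors are all mutually
    # adjacent); removing such pixels never breaks connectivity
    changed = True
    while changed:
        changed = False
        for p in sorted(pixels):
            nbrs = set(_neighbors(p, pixels))
            if len(nbrs) >= 2 and _adjacency_components(nbrs) == 1:
                pixels.discard(p)
                changed = True

    out = np.zeros_like(skeleton)
    rr = [p[0] for p in pixels]
    cc = [p[1] for p in pixels]
    out[rr, cc] = True
    return out


@dataclass
class SkeletonGraph:
    """Skeleton as a graph: node = skeleton pixel ``(row, col)`` with a
    distance attribute ``d``; edge = 8-adjacent pixel pair."""

    graph: nx.Graph
    base_node: tuple[int, int] | None = field(default=None)

    @property
    def nodes(self):
        return self.graph.nodes

    def d(self, node) -> float:
        return self.graph.nodes[node]["d"]

    @cached_property
    def extremal_nodes(self) -> list[tuple[int, int]]:
        """Degree-1 nodes (skeleton tips)."""
        return [n for n, deg in self.graph.degree() if deg == 1]

    @cached_property
    def junction_nodes(self) -> set[tuple[int, int]]:
        """Degree->=3 nodes (branch points by raw adjacency)."""
        return {n for n, deg in self.graph.degree() if deg >= 3}

    @cached_property
    def branch_nodes(self) -> set[tuple[int, int]]:
        """Pixels of genuine fork clusters (see :func:`fork_pixels`)."""
        return fork_pixels(set(self.graph.nodes))

    def path(self, a, b) -> list[tuple[int, int]]:
        return nx.shortest_path(self.graph, a, b)


def build_graph(skeleton: np.ndarray, distance: np.ndarray) -> SkeletonGraph:
    """Convert a skeleton raster into an annotated ``SkeletonGraph``.

    If the skeleton raster is disconnected (it should not be, for a
    single-component mask), the largest connected component is kept and
    a warning logged.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    coords = list(zip(*map(list, np.nonzero(skeleton))))
    if not coords:
        raise EmptyMaskError("cannot build a graph from an empty skeleton")
    g = nx.Graph()
    pixel_set = set(coords)
    for p in coords:
        g.add_node(p, d=float(distance[p]))
    for r, c in coords:
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):  # forward half of 8-nbrs
            q = (r + dr, c + dc)
            if q in pixel_set:
                g.add_edge((r, c), q)
    if nx.number_connected_components(g) > 1:
        log.warning("skeleton graph is disconnected; keeping the largest component")
        largest = max(nx.connected_components(g), key=len)
        g = g.subgraph(largest).copy()
    return SkeletonGraph(graph=g)


def find_base_node(graph: SkeletonGraph) -> tuple[int, int]:
    """Extremal node with the maximal row index (lowest point in the
    image); ties broken by the smaller column.  Assumes petiole-down
    orientation.  Sets ``graph.base_node`` as a side effect."""
    ext = graph.extremal_nodes
    if not ext:
        raise TopologyError("skeleton graph has no extremal (degree-1) node")
    base = min(ext, key=lambda rc: (-rc[0], rc[1]))
    graph.base_node = base
    return base


def path_chain_length(path) -> float:
    """Euclidean chain length of an 8-connected pixel path: 1 per axial
    step, sqrt(2) per diagonal step."""
    if len(path) < 2:
        return 0.0
    arr = np.asarray(path, dtype=float)
    steps = np.abs(np.diff(arr, axis=0))
    return float(np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0).sum())
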