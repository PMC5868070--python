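"""Cut-node detection and leaf dissection on the skeleton graph.

Skeleton pixels inside a leaflet sit farther from the leaf outline than
pixels on the rachis or a petiolule, so their distance-transform values
separate into two clusters.  A 1-D two-component Gaussian mixture gives
a rough labeling into leaflet pixels *L* (larger distances) and
stem pixels *R*.  Because that labeling is noisy, the cut point on each
base-to-tip path is chosen to minimize the number of label
misclassifications

    M(k) = |{1..k} ∩ L| + |{k+1..N} ∩ R|,

i.e. the first index k at which "stem before k, leaflet after k" best
explains the observed labels.  The cut node and the outline chord
(b1, b2) built from it then sever each leaflet from the rest of the
leaf, yielding a partition into petiole, rachis, petiolules and
leaflets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label
from sklearn.mixture import GaussianMixture

from .errors import (
    BoundaryCutError,
    DegenerateClusterError,
    DissectionError,
)
from .skeleton import SkeletonGraph, path_chain_length

log = logging.getLogger(__name__)

__all__ = [
    "SkeletonLabeling",
    "LeafletCut",
    "CutNodeSet",
    "LeafDissection",
    "cluster_distance_values",
    "cut_index_on_path",
    "find_cut_nodes",
    "boundary_cut",
    "outline_pixels",
    "dissect",
    "order_leaflets",
]


@dataclass
class SkeletonLabeling:
    """Per-node L/R labels from the 2-Gaussian fit on distance values.

    ``L`` marks leaflet nodes (the larger-mean component), ``R`` marks
    rachis/petiolule nodes.
    """

    labels: dict[tuple[int, int], str]
    means: tuple[float, float]  # (R mean, L mean)
    variances: tuple[float, float]

    def __getitem__(self, node) -> str:
        return self.labels[node]


def cluster_distance_values(
    graph: SkeletonGraph, random_state: int = 0
) -> SkeletonLabeling:
    """2-component 1-D Gaussian mixture on skeleton distance values.

    The component with the larger mean is the leaflet class *L*; a leaf
    with no blade/stem contrast (all distances equal) is rejected.
    """
    nodes = list(graph.graph.nodes)
    d = np.array([graph.d(n) for n in nodes])
    if len(nodes) < 2 or np.ptp(d) <= 1e-12:
        raise DegenerateClusterError(
            "all skeleton distance values are identical; no blade/stem contrast"
        )
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=2)
    comp = gm.fit_predict(d.reshape(-1, 1))
    means = gm.means_.ravel()
    l_comp = int(np.argmax(means))
    labels = {
        n: ("L" if c == l_comp else "R") for n, c in zip(nodes, comp)
    }
    variances = gm.covariances_.ravel()
    r_comp = 1 - l_comp
    return SkeletonLabeling(
        labels=labels,
        means=(float(means[r_comp]), float(means[l_comp])),
        variances=(float(variances[r_comp]), float(variances[l_comp])),
    )


def cut_index_on_path(labels) -> tuple[int, int]:
    """First index k in 0..N minimizing the misclassification count
    M(k) = |{1..k} ∩ L| + |{k+1..N} ∩ R|.

    ``labels`` is a sequence of 'L'/'R' along the path (base first).
    k = 0 means the whole path is leaflet, k = N means no leaflet on
    this path.  Returns ``(k, M(k))``.
    """
    lab = np.asarray(list(labels))
    is_l = lab == "L"
    is_r = ~is_l
    cum_l = np.concatenate([[0], np.cumsum(is_l)])
    cum_r = np.concatenate([[0], np.cumsum(is_r)])
    m = cum_l + (cum_r[-1] - cum_r)  # M(k) for k = 0..N
    k = int(np.argmin(m))  # argmin returns the first minimum
    return k, int(m[k])


@dataclass
class LeafletCut:
    """One leaflet's cut geometry on the skeleton."""

    cut: tuple[int, int]
    branching: tuple[int, int]
    seed: tuple[int, int]  # first skeleton node on the leaflet side
    m_value: int
    cut_index: int
    path: list = field(repr=False, default_factory=list)
    b1: tuple[int, int] | None = None
    b2: tuple[int, int] | None = None
    flagged: str | None = None  # reason, if the leaflet failed a stage
    # filled by order_leaflets
    rank: int | None = None
    side: str | None = None


@dataclass
class CutNodeSet:
    """Cut/branching nodes and boundary pairs, one entry per leaflet."""

    leaflets: list[LeafletCut]
    simple_leaf: bool = False

    def __len__(self) -> int:
        return len(self.leaflets)


def find_cut_nodes(
    graph: SkeletonGraph,
    labeling: SkeletonLabeling,
    base: tuple[int, int],
) -> CutNodeSet:
    """Locate one cut node per leaflet.

    Every simple path from the base to an extremal node is scanned with
    :func:`cut_index_on_path`.  Paths ending in the same connected
    L-region belong to the same leaflet; if their cut nodes disagree,
    the candidate with the smallest M value wins (ties: the smallest
    index along its path).  The branching node is the last junction
    strictly before the cut node, or the base if there is none.
    """
    g = graph.graph
    # connected L-regions on the skeleton = candidate leaflets
    l_nodes = [n for n in g.nodes if labeling[n] == "L"]
    l_sub = g.subgraph(l_nodes)
    comp_of: dict[tuple[int, int], int] = {}
    for i, comp in enumerate(nx.connected_components(l_sub)):
        for n in comp:
            comp_of[n] = i

    candidates: dict[int, list[LeafletCut]] = {}
    for ext in graph.extremal_nodes:
        if ext == base:
            continue
        path = graph.path(base, ext)
        n = len(path)
        labs = [labeling[p] for p in path]
        k, m = cut_index_on_path(labs)
        if not (1 <= k <= n - 1):
            continue  # all-leaflet or no-leaflet path
        cut = path[k - 1]  # node k in 1-based enumeration: last stem node
        seed = path[k]  # first leaflet-side node
        region = comp_of.get(ext)
        if region is None:
            # tip not labeled L (e.g. thin leaflet apex): use the
            # region of the first L node after the cut
            region = next(
                (comp_of[p] for p in path[k:] if p in comp_of), None
            )
            if region is None:
                continue
        branching = base
        for p in path[: k - 1]:
            if p in graph.branch_nodes:
                branching = p
        cand = LeafletCut(
            cut=cut, branching=branching, seed=seed, m_value=m, cut_index=k, path=path
        )
        candidates.setdefault(region, []).append(cand)

    leaflets = []
    for region, cands in sorted(candidates.items()):
        best = min(cands, key=lambda c: (c.m_value, c.cut_index))
        leaflets.append(best)
    simple = len(leaflets) == 1
    if simple:
        log.info("single leaflet region found: simple-leaf case")
    if not leaflets:
        raise DissectionError("no cut node found on any base-to-tip path")
    return CutNodeSet(leaflets=leaflets, simple_leaf=simple)


def outline_pixels(mask: np.ndarray) -> np.ndarray:
    """(N, 2) array of foreground pixels 8-adjacent to background
    (including the image frame)."""
    mask = np.asarray(mask, dtype=bool)
    eroded = binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(mask & ~eroded)


def _b2_candidates(outline: np.ndarray, c) -> tuple[tuple[int, int], np.ndarray]:
    """b1 plus all outline points satisfying the opposite-side
    constraint d(b1, b2) > d(c, b2), ordered by distance to c (ties:
    smaller row, then column)."""
    if len(outline) == 0:
        raise BoundaryCutError("mask has no outline")
    c_arr = np.asarray(c, dtype=float)
    dist_c = np.hypot(*(outline - c_arr).T)
    order = np.lexsort((outline[:, 1], outline[:, 0], dist_c))
    b1 = tuple(int(v) for v in outline[order[0]])
    dist_b1 = np.hypot(*(outline - np.asarray(b1, dtype=float)).T)
    if dist_c[order[0]] == 0.0:
        # c lies on the outline itself (b1 = c): the opposite-side
        # constraint is vacuous, so b2 is the nearest other outline point
        ok = dist_b1 > 0
    else:
        ok = dist_b1 > dist_c
    if not ok.any():
        raise BoundaryCutError(
            f"no outline point opposite to b1={b1} for cut node {tuple(c)}"
        )
    sub = outline[ok]
    order2 = np.lexsort((sub[:, 1], sub[:, 0], dist_c[ok]))
    return b1, sub[order2]


def boundary_cut(mask: np.ndarray, c: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int]]:
    """Outline pair (b1, b2) whose chord severs the leaflet at cut node c.

    b1 is the outline point nearest to c; b2 is the nearest outline
    point on the opposite side, i.e. subject to d(b1, b2) > d(c, b2).
    Ties broken by smaller row, then column.
    """
    b1, cands = _b2_candidates(outline_pixels(mask), c)
    return b1, tuple(int(v) for v in cands[0])


def chord_pixels(b1, b2, shape=None, extend: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """4-connected raster of the b1-b2 chord, slightly extended.

    A plain Bresenham line is 8-connected, and removing it from an
    8-connected region leaves diagonal leaks across its diagonal steps;
    inserting one extra pixel per diagonal step makes the cut tight.
    The line is also extended ``extend`` px beyond each endpoint:
    the endpoints lie exactly on the jagged discrete outline, where
    foreground pixels diagonal to them would otherwise bridge the cut.
    """
    p1 = np.asarray(b1, dtype=float)
    p2 = np.asarray(b2, dtype=float)
    v = p2 - p1
    n = np.hypot(*v)
    if n > 0 and extend > 0:
        u = v / n
        p1 = p1 - extend * u
        p2 = p2 + extend * u
    e1 = np.round(p1).astype(int)
    e2 = np.round(p2).astype(int)
    if shape is not None:
        e1 = np.clip(e1, 0, np.asarray(shape) - 1)
        e2 = np.clip(e2, 0, np.asarray(shape) - 1)
    rr, cc = draw_line(e1[0], e1[1], e2[0], e2[1])
    extra_r, extra_c = [], []
    for i in range(1, len(rr)):
        if rr[i] != rr[i - 1] and cc[i] != cc[i - 1]:
            extra_r.append(rr[i])
            extra_c.append(cc[i - 1])
    rr = np.concatenate([rr, np.asarray(extra_r, dtype=rr.dtype)])
    cc = np.concatenate([cc, np.asarray(extra_c, dtype=cc.dtype)])
    if shape is not None:
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        rr, cc = rr[ok], cc[ok]
    return rr, cc


def _chord_severs(mask, b1, b2, seed, base, other_seeds=()) -> bool:
    """True if removing the b1-b2 chord separates seed from base while
    leaving every other leaflet's seed outside the severed component."""
    rr, cc = chord_pixels(b1, b2, mask.shape)
    work = mask.copy()
    work[rr, cc] = False
    comp = cc_label(work, connectivity=2)
    bc = comp[base]
    if bc == 0:
        return False
    sc = comp[seed]
    if sc == 0:  # seed fell on the chord; probe its neighborhood
        r, c = seed
        patch = comp[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
        vals = patch[(patch != 0) & (patch != bc)]
        if len(vals) == 0:
            return False
        sc = int(vals[0])
    if sc == bc:
        return False
    for other in other_seeds:
        if comp[other] == sc:
            return False
    return True


def attach_boundary_pairs(
    mask: np.ndarray,
    cuts: CutNodeSet,
    base: tuple[int, int] | None = None,
    max_candidates: int = 100,
) -> CutNodeSet:
    """Compute (b1, b2) for every cut node; failures flag the leaflet.

    With ``base`` given, b2 is the nearest constraint-satisfying
    candidate whose chord actually severs the leaflet from the leaf
    body (on discrete outlines the globally nearest candidate can be a
    near-tangential point whose chord cuts nothing).
    """
    outline = outline_pixels(mask)
    for lc in cuts.leaflets:
        if base is None:
            try:
                b1, cands = _b2_candidates(outline, lc.cut)
            except BoundaryCutError as exc:
                lc.flagged = f"boundary-cut: {exc}"
                continue
            lc.b1, lc.b2 = b1, tuple(int(v) for v in cands[0])
            continue
        # The cut node sits exactly at the stalk/blade transition, where
        # the shape is locally wide; if no nearby chord severs there,
        # retreat the chord anchor down the stalk (the reported cut node
        # is unchanged) until the chord crosses a thin cross-section.
        # Candidates are kept local: a severing chord should cross one
        # stalk, not slice across the whole leaf.
        other_seeds = [o.seed for o in cuts.leaflets if o is not lc]
        chosen = None
        max_back = min(8, max(lc.cut_index - 1, 0))
        for back in range(0, max_back + 1):
            anchor = lc.path[lc.cut_index - 1 - back] if lc.path else lc.cut
            try:
                b1, cands = _b2_candidates(outline, anchor)
            except BoundaryCutError:
                continue
            radius = max(6.0, 4.0 * np.hypot(b1[0] - anchor[0], b1[1] - anchor[1]) + 3.0)
            for cand in cands[:max_candidates]:
                b2 = tuple(int(v) for v in cand)
                if np.hypot(b2[0] - anchor[0], b2[1] - anchor[1]) > radius:
                    break  # candidates are distance-ordered
                if _chord_severs(mask, b1, b2, lc.seed, base, other_seeds):
                    chosen = (b1, b2)
                    break
            if chosen:
                break
        if chosen is None:
            lc.flagged = "boundary-cut: no severing chord found near the cut node"
        else:
            lc.b1, lc.b2 = chosen
    return cuts


@dataclass
class LeafDissection:
    """Partition of the foreground into petiole, rachis, petiolules and
    leaflets.

    ``labels`` is an int raster: 0 background, 1 petiole, 2 rachis,
    then one id per petiolule and leaflet; ``legend`` maps ids to class
    names (``petiolule_i`` / ``leaflet_i`` use the leaflet order of
    ``cuts.leaflets``).
    """

    labels: np.ndarray
    legend: dict[int, str]
    cuts: CutNodeSet
    terminal_index: int | None = None
    main_path: list = field(default_factory=list, repr=False)

    PETIOLE, RACHIS = 1, 2

    def class_mask(self, name: str) -> np.ndarray:
        ids = [i for i, n in self.legend.items() if n == name]
        if not ids:
            return np.zeros_like(self.labels, dtype=bool)
        return np.isin(self.labels, ids)

    def leaflet_mask(self, i: int) -> np.ndarray:
        return self.class_mask(f"leaflet_{i}")

    @property
    def n_leaflets(self) -> int:
        return sum(1 for n in self.legend.values() if n.startswith("leaflet_"))


def _terminal_index(graph: SkeletonGraph, cuts: CutNodeSet, base) -> int:
    """Leaflet whose cut node is graph-farthest from the base."""
    lengths = [
        nx.shortest_path_length(graph.graph, base, lc.cut) for lc in cuts.leaflets
    ]
    return int(np.argmax(lengths))


def dissect(
    mask: np.ndarray,
    graph: SkeletonGraph,
    cuts: CutNodeSet,
    base: tuple[int, int],
) -> LeafDissection:
    """Partition the foreground using the b1–b2 chords.

    Each chord is rasterized and removed; the connected component
    holding the leaflet-side skeleton seed becomes that leaflet (the
    chord pixels are given back to it).  Remaining stem pixels are
    attributed to the nearest labeled skeleton segment: base→first
    branching node = petiole, the rest of the main axis = rachis, each
    branching→cut path = that leaflet's petiolule.
    """
    mask = np.asarray(mask, dtype=bool)
    def is_active(lc):
        return lc.flagged is None and lc.b1 is not None

    work = mask.copy()
    chords: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, lc in enumerate(cuts.leaflets):
        if not is_active(lc):
            continue
        rr, cc = chord_pixels(lc.b1, lc.b2, mask.shape)
        keep = mask[rr, cc]
        chords[i] = (rr[keep], cc[keep])
        work[rr[keep], cc[keep]] = False

    comp = cc_label(work, connectivity=2)
    base_comp = comp[base]
    labels = np.zeros(mask.shape, dtype=np.int32)
    legend: dict[int, str] = {1: "petiole", 2: "rachis"}
    next_id = 3

    leaflet_ids: dict[int, int] = {}
    used_comps: dict[int, int] = {}
    for i, lc in enumerate(cuts.leaflets):
        if not is_active(lc):
            continue
        cid = comp[lc.seed]
        if cid == 0:
            # seed fell on a chord pixel; probe its neighbors
            r, c = lc.seed
            patch = comp[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
            vals = patch[(patch != 0) & (patch != base_comp)]
            cid = int(vals[0]) if len(vals) else 0
        if cid == 0 or cid == base_comp:
            lc.flagged = "dissection: chord did not separate the leaflet"
            continue
        if cid in used_comps:
            lc.flagged = "dissection: chord merged two leaflets"
            cuts.leaflets[used_comps[cid]].flagged = (
                "dissection: chord merged two leaflets"
            )
            continue
        used_comps[cid] = i
        lid = next_id
        next_id += 1
        legend[lid] = f"leaflet_{i}"
        leaflet_ids[i] = lid
        labels[comp == cid] = lid
        rr, cc = chords[i]
        free = labels[rr, cc] == 0
        labels[rr[free], cc[free]] = lid

    if not leaflet_ids:
        raise DissectionError("no leaflet could be separated from the leaf body")

    # --- stem skeleton labeling -------------------------------------
    sep_i = _terminal_index(graph, cuts, base)
    terminal_lc = cuts.leaflets[sep_i]
    main_path = graph.path(base, terminal_lc.cut)
    main_set = set(main_path)

    branchings = {lc.branching for i, lc in enumerate(cuts.leaflets) if i in leaflet_ids}
    first_branch_pos = None
    for pos, node in enumerate(main_path):
        if node in branchings and node != base:
            first_branch_pos = pos
            break

    stem_label_of: dict[tuple[int, int], int] = {}
    if first_branch_pos is None:
        for node in main_path:
            stem_label_of[node] = LeafDissection.PETIOLE
    else:
        for node in main_path[:first_branch_pos]:
            stem_label_of[node] = LeafDissection.PETIOLE
        for node in main_path[first_branch_pos:]:
            stem_label_of[node] = LeafDissection.RACHIS

    for i, lc in enumerate(cuts.leaflets):
        if i not in leaflet_ids or i == sep_i:
            continue
        pet_path = graph.path(lc.branching, lc.cut)
        pid = next_id
        next_id += 1
        legend[pid] = f"petiolule_{i}"
        for node in pet_path[1:]:
            if node not in main_set:
                stem_label_of[node] = pid

    stem_nodes = list(stem_label_of)
    tree = cKDTree(np.asarray(stem_nodes, dtype=float))
    stem_pixels = np.argwhere(mask & (labels == 0))
    if len(stem_pixels):
        _, idx = tree.query(stem_pixels)
        vals = np.array([stem_label_of[stem_nodes[j]] for j in idx], dtype=np.int32)
        labels[stem_pixels[:, 0], stem_pixels[:, 1]] = vals

    return LeafDissection(
        labels=labels,
        legend=legend,
        cuts=cuts,
        terminal_index=sep_i,
        main_path=main_path,
    )


def order_leaflets(dissection: LeafDissection, graph: SkeletonGraph) -> LeafDissection:
    """Assign rank and side to every separated leaflet.

    The terminal leaflet gets rank 0 / side "terminal".  Lateral
    leaflets are ranked per side by increasing graph distance from
    their branching node to the terminal branching node (rank 1 is the
    pair nearest the apex).  Side is the sign of the 2-D cross product
    between the local rachis direction (toward the terminal leaflet)
    and the branching→cut direction, evaluated in an upright Cartesian
    frame; positive means left.
    """
    cuts = dissection.cuts
    term = dissection.terminal_index
    main_path = dissection.main_path
    pos_on_main = {node: i for i, node in enumerate(main_path)}
    term_branch = cuts.leaflets[term].branching

    laterals = []
    for i, lc in enumerate(cuts.leaflets):
        if lc.flagged is not None:
            continue
        if i == term:
            lc.rank, lc.side = 0, "terminal"
            continue
        dist = nx.shortest_path_length(graph.graph, lc.branching, term_branch)
        # local rachis direction at the branching node, toward the apex
        p = pos_on_main.get(lc.branching)
        if p is None:
            # branching off the main path (should not happen); fall back
            # to the path toward the terminal branching node
            path = graph.path(lc.branching, term_branch)
            nxt = path[min(5, len(path) - 1)]
        else:
            nxt = main_path[min(p + 5, len(main_path) - 1)]
        v1 = (nxt[1] - lc.branching[1], -(nxt[0] - lc.branching[0]))  # (x, y up)
        v2 = (lc.cut[1] - lc.branching[1], -(lc.cut[0] - lc.branching[0]))
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        lc.side = "left" if cross > 0 else "right"
        laterals.append((i, dist))

    for side in ("left", "right"):
        side_list = [
            (i, d) for i, d in laterals if cuts.leaflets[i].side == side
        ]
        side_list.sort(key=lambda t: t[1])
        for rank, (i, _) in enumerate(side_list, start=1):
            cuts.leaflets[i].rank = rank
    return dissection
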