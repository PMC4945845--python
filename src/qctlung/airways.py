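"""Airway-tree extraction and per-generation lumen/wall morphometry.

The bronchial tree is recovered in three stages:

1. ``segment_airway_tree`` — leak-controlled region growing of the air
   lumen.  The HU threshold is relaxed stepwise from near pure air upward;
   any relaxation step whose accepted-volume growth exceeds a leak ratio is
   rolled back, which stops the region from spilling through a thin or
   broken airway wall into the parenchyma.
2. ``extract_centerline_tree`` — 3-D skeletonization of the lumen mask,
   condensation of the skeleton voxel graph into branch segments, spur
   pruning, and breadth-first generation labeling from the tracheal end
   (trachea = generation 1).
3. ``measure_segment`` — at cross-sections perpendicular to the smoothed
   centerline, rays cast outward locate the inner (lumen) and outer wall
   edges at the half-maximum HU crossings of the wall attenuation bump;
   luminal area comes from the polygon of inner-edge radii and wall
   thickness from the mean inner-to-outer edge distance.

Per-generation summaries normalise luminal area to the subject's total
lung capacity (TLC) and wall thickness to the luminal area of the same
generation (a wall-to-radius ratio is emitted alongside).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .core import CTVolume, RegionMask

__all__ = [
    "AirwaySegment",
    "AirwayTree",
    "GenerationSummary",
    "segment_airway_tree",
    "extract_centerline_tree",
    "measure_segment",
    "measure_tree",
    "per_generation_summary",
    "normalize_to_subject",
    "tree_to_json",
    "tree_from_json",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class AirwaySegment:
    """One branch of the airway tree between consecutive bifurcations."""

    id: int
    parent_id: int | None
    generation: int  # trachea = 1
    centerline: np.ndarray  # (n, 3) ordered points, mm
    mean_lumen_area: float = float("nan")  # mm^2
    mean_wall_thickness: float = float("nan")  # mm
    n_cross_sections: int = 0
    quality_flag: str = "unmeasured"  # unmeasured | ok | unreliable
    # ground-truth geometry, populated only for phantom truth trees
    radius_mm: float | None = None
    wall_mm: float | None = None

    @property
    def length_mm(self) -> float:
        d = np.diff(np.asarray(self.centerline, dtype=float), axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())


@dataclass
class AirwayTree:
    """Rooted airway tree with generation labels (trachea = generation 1)."""

    segments: list[AirwaySegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        roots = [s for s in self.segments if s.parent_id is None]
        if self.segments and len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {len(roots)}")
        by_id = {s.id: s for s in self.segments}
        for s in self.segments:
            if s.parent_id is not None:
                parent = by_id.get(s.parent_id)
                if parent is None:
                    raise ValueError(f"segment {s.id} references missing parent")
                if s.generation != parent.generation + 1:
                    raise ValueError(
                        f"segment {s.id}: generation {s.generation} != "
                        f"parent generation {parent.generation} + 1"
                    )

    @property
    def root(self) -> AirwaySegment:
        return next(s for s in self.segments if s.parent_id is None)

    @property
    def max_generation(self) -> int:
        return max(s.generation for s in self.segments)

    def children(self, seg_id: int) -> list[AirwaySegment]:
        return [s for s in self.segments if s.parent_id == seg_id]


@dataclass
class GenerationSummary:
    """Segment-averaged morphometry of one airway generation."""

    generation: int
    mean_area: float  # mm^2
    mean_wall: float  # mm
    n_segments: int
    area_over_tlc: float = float("nan")  # mm^2 / L
    wall_over_area: float = float("nan")  # mm / mm^2
    wall_over_radius: float = float("nan")  # dimensionless
    flag: str = "ok"  # ok | absent | unreliable


# ---------------------------------------------------------------------------
# lumen segmentation


def segment_airway_tree(
    volume: CTVolume,
    seed_point: tuple[int, int, int],
    initial_threshold_hu: float = -950.0,
    final_threshold_hu: float = -400.0,
    step_hu: float = 25.0,
    leak_ratio: float = 2.0,
) -> RegionMask:
    """Leak-controlled region growing of the airway lumen.

    Starting from the seed's connected component below
    ``initial_threshold_hu``, the threshold is relaxed in ``step_hu``
    increments up to ``final_threshold_hu``.  A step that multiplies the
    accepted volume by more than ``leak_ratio`` is interpreted as the
    region bursting through an airway wall; growth is rolled back to the
    last safe threshold and stops.

    Raises
    ------
    ValueError
        If the seed voxel is not in air, or the very first component is
        border-connected (seed in ambient air — unsegmentable).
    """
    seed = tuple(int(c) for c in seed_point)
    hu = volume.values
    if hu[seed] >= initial_threshold_hu:
        raise ValueError(
            f"seed voxel HU {hu[seed]:.0f} is not below the initial airway "
            f"threshold {initial_threshold_hu:.0f}"
        )

    def seed_component(thr: float) -> np.ndarray:
        labels, _ = ndimage.label(hu < thr, structure=_STRUCT6)
        return labels == labels[seed]

    current = seed_component(initial_threshold_hu)
    if _touches_border(current):
        raise ValueError("unsegmentable: seed region is connected to the grid border")
    thresholds = np.arange(
        initial_threshold_hu + step_hu, final_threshold_hu + 0.5 * step_hu, step_hu
    )
    for thr in thresholds:
        grown = seed_component(thr)
        if grown.sum() > leak_ratio * current.sum() or _touches_border(grown):
            break  # leak: roll back past this step
        current = grown
    return RegionMask(mask=current, label="airway_lumen")


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


# ---------------------------------------------------------------------------
# skeleton -> tree

_OFFSETS26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


def _skeleton_graph(skel: np.ndarray, spacing: np.ndarray) -> nx.Graph:
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    G = nx.Graph()
    G.add_nodes_from(range(len(coords)))
    for i, c in enumerate(coords):
        for off in _OFFSETS26:
            nb = tuple(c + off)
            j = index.get(nb)
            if j is not None and j > i:
                w = float(np.linalg.norm(off * spacing))
                G.add_edge(i, j, weight=w)
    for i, c in enumerate(coords):
        G.nodes[i]["voxel"] = tuple(int(v) for v in c)
    return G


def extract_centerline_tree(
    lumen: RegionMask,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    prune_mm: float = 3.0,
    root_hint: tuple[int, int, int] | None = None,
) -> AirwayTree:
    """Skeletonize a lumen mask and condense it into a generation-labeled tree.

    The skeleton voxel graph is reduced to a segment graph whose nodes are
    endpoints and bifurcation clusters.  Leaf segments shorter than
    ``prune_mm`` are removed as skeletonization spurs (pass-through nodes
    left behind are merged).  The root is the endpoint nearest
    ``root_hint``, or the endpoint with the lowest slice index (tracheal
    end) when no hint is given; generations count bifurcations from the
    root, trachea = 1.
    """
    mask = lumen.mask
    labels, ncomp = ndimage.label(mask, structure=_STRUCT26)
    if ncomp == 0:
        raise ValueError("empty lumen mask")
    if ncomp > 1:
        raise ValueError(f"lumen mask has {ncomp} connected components, expected 1")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)

    skel = skeletonize(mask)
    G = _skeleton_graph(skel, spacing)
    if G.number_of_nodes() == 0:
        raise ValueError("skeletonization produced no voxels")
    if G.number_of_edges() >= G.number_of_nodes():
        warnings.warn("cyclic skeleton; breaking cycles at longest edges",
                      stacklevel=2)
        G = nx.minimum_spanning_tree(G, weight="weight")
    if root_hint is not None:
        # topology-preserving thinning recedes far into blunt tube ends and
        # can consume the proximal trachea entirely; graft a path from the
        # hint through the mask back onto the skeleton
        _anchor_root(G, mask, tuple(int(c) for c in root_hint), spacing)

    seg_graph = _condense(G)
    _prune(seg_graph, prune_mm)

    # root selection among segment-graph leaves
    leaves = [n for n in seg_graph.nodes if seg_graph.degree(n) == 1]
    if not leaves:  # single isolated chain collapsed to nothing
        raise ValueError("no endpoints found in skeleton")

    def leaf_voxel(n):
        return seg_graph.nodes[n]["voxel"]

    if root_hint is not None:
        hint = np.asarray(root_hint, dtype=float)
        root = min(leaves, key=lambda n: np.linalg.norm((np.asarray(leaf_voxel(n)) - hint) * spacing))
    else:
        root = min(leaves, key=lambda n: leaf_voxel(n))  # lowest slice, then row/col

    # BFS over the segment graph assigning generations
    segments: list[AirwaySegment] = []
    next_id = [0]

    def emit(path_voxels, generation, parent_id) -> int:
        sid = next_id[0]
        next_id[0] += 1
        pts = np.asarray(path_voxels, dtype=float) * spacing + origin
        segments.append(
            AirwaySegment(id=sid, parent_id=parent_id, generation=generation,
                          centerline=pts)
        )
        return sid

    visited_edges: set[frozenset] = set()
    stack = [(root, None, 0)]  # (node, parent segment id, parent generation)
    while stack:
        node, parent_sid, parent_gen = stack.pop()
        for nb in seg_graph.neighbors(node):
            for key, data in seg_graph[node][nb].items():
                ek = frozenset([(node, nb, key), (nb, node, key)])
                if ek in visited_edges:
                    continue
                visited_edges.add(ek)
                path = data["path"]
                if path[0] != seg_graph.nodes[node]["voxel"]:
                    path = path[::-1]
                sid = emit(path, parent_gen + 1, parent_sid)
                stack.append((nb, sid, parent_gen + 1))
    tree = AirwayTree(segments=segments)
    _extend_root(tree, mask, spacing, origin)
    return tree


def _extend_root(
    tree: AirwayTree, mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray
) -> None:
    """Extend the root centerline proximally through the lumen mask.

    Topology-preserving thinning recedes from the blunt tracheal end by up
    to one lumen radius or more; marching the root segment's direction
    backwards through the mask recovers the measurable tracheal length.
    """
    root = tree.root
    pts = np.asarray(root.centerline, dtype=float)
    if pts.shape[0] < 2:
        return
    k = min(5, pts.shape[0] - 1)
    d = pts[0] - pts[k]
    nrm = np.linalg.norm(d)
    if nrm == 0:
        return
    d /= nrm
    step = float(spacing.min())
    new_pts = []
    p = pts[0].copy()
    for _ in range(int(200 / step)):
        p = p + d * step
        idx = np.round((p - origin) / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= mask.shape) or not mask[tuple(idx)]:
            break
        new_pts.append(p.copy())
    if len(new_pts) > 2:
        new_pts = new_pts[:-2]  # stay clear of the end cap
        root.centerline = np.vstack([np.asarray(new_pts)[::-1], pts])


def _anchor_root(
    G: nx.Graph, mask: np.ndarray, root_hint: tuple[int, int, int],
    spacing: np.ndarray, near_vox: float = 3.0,
) -> None:
    """Graft a mask-interior path from ``root_hint`` onto the skeleton.

    No-op when the hint is outside the mask or already within ``near_vox``
    voxels of a skeleton voxel.  The grafted chain restores the proximal
    end of the root branch; any stub it creates at the attachment point is
    removed later by spur pruning.
    """
    if not mask[root_hint]:
        return
    vox_to_node = {G.nodes[n]["voxel"]: n for n in G.nodes}
    hint = np.asarray(root_hint, float)
    dists = [np.linalg.norm((np.asarray(v) - hint)) for v in vox_to_node]
    if min(dists) <= near_vox:
        return
    # BFS through the mask from the hint to the nearest skeleton voxel
    from collections import deque

    queue = deque([root_hint])
    parent: dict[tuple, tuple | None] = {root_hint: None}
    hit = None
    while queue:
        cur = queue.popleft()
        if cur in vox_to_node:
            hit = cur
            break
        for off in _OFFSETS26:
            nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
            if (nb not in parent
                    and all(0 <= nb[k] < mask.shape[k] for k in range(3))
                    and mask[nb]):
                parent[nb] = cur
                queue.append(nb)
    if hit is None:
        return
    path = [hit]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    # path runs hit -> hint; add chain nodes and edges
    next_id = max(G.nodes) + 1
    prev = vox_to_node[hit]
    for vox in path[1:]:
        G.add_node(next_id, voxel=vox)
        w = float(np.linalg.norm((np.asarray(vox) - np.asarray(G.nodes[prev]["voxel"])) * spacing))
        G.add_edge(prev, next_id, weight=w)
        prev = next_id
        next_id += 1


def _condense(G: nx.Graph) -> nx.MultiGraph:
    """Collapse the skeleton voxel graph to a segment multigraph.

    Nodes are endpoints (degree 1) and bifurcation clusters (connected
    groups of degree>=3 voxels); each edge carries the ordered voxel path
    of one branch and its length in mm.
    """
    deg = dict(G.degree())
    junctions = {n for n, d in deg.items() if d >= 3}
    # cluster junction voxels that touch each other
    jsub = G.subgraph(junctions)
    cluster_of: dict[int, int] = {}
    cluster_voxel: dict[int, tuple] = {}
    for ci, comp in enumerate(nx.connected_components(jsub)):
        comp = list(comp)
        # representative voxel: centroid-nearest member
        vox = np.array([G.nodes[n]["voxel"] for n in comp], dtype=float)
        centroid = vox.mean(axis=0)
        rep = comp[int(np.argmin(((vox - centroid) ** 2).sum(axis=1)))]
        for n in comp:
            cluster_of[n] = ci
        cluster_voxel[ci] = G.nodes[rep]["voxel"]

    S = nx.MultiGraph()

    def node_key(n):
        if n in cluster_of:
            return ("j", cluster_of[n])
        return ("e", n)

    for n in G.nodes:
        if deg[n] == 1:
            S.add_node(("e", n), voxel=G.nodes[n]["voxel"])
    for ci, vox in cluster_voxel.items():
        S.add_node(("j", ci), voxel=vox)

    visited: set[frozenset] = set()
    terminals = [n for n in G.nodes if deg[n] != 2]
    for t in terminals:
        for nb in G.neighbors(t):
            if nb in cluster_of and t in cluster_of and cluster_of[nb] == cluster_of[t]:
                continue  # internal cluster edge
            first = frozenset([t, nb])
            if first in visited:
                continue
            # walk the chain
            path = [t, nb]
            visited.add(first)
            prev, cur = t, nb
            while deg[cur] == 2:
                nxt = next(m for m in G.neighbors(cur) if m != prev)
                visited.add(frozenset([cur, nxt]))
                path.append(nxt)
                prev, cur = cur, nxt
            a, b = node_key(path[0]), node_key(path[-1])
            if a not in S or b not in S:
                continue
            vox_path = [G.nodes[p]["voxel"] for p in path]
            length = sum(
                float(np.linalg.norm(np.subtract(vox_path[i + 1], vox_path[i])))
                for i in range(len(vox_path) - 1)
            )
            S.add_edge(a, b, path=vox_path, length=length)
    # isolated chain with no terminals at all cannot occur in an acyclic graph
    return S


def _prune(S: nx.MultiGraph, prune_mm: float) -> None:
    """Remove short leaf spurs in place, then merge pass-through nodes."""
    changed = True
    while changed:
        changed = False
        for n in list(S.nodes):
            if S.degree(n) == 1 and n[0] == "e":
                (u, v, key) = next(iter(S.edges(n, keys=True)))
                if S[u][v][key]["length"] < prune_mm and S.degree(v if u == n else u) > 1:
                    S.remove_node(n)
                    changed = True
        # merge nodes that became pass-through (degree 2) junctions
        for n in list(S.nodes):
            if S.degree(n) == 2 and n[0] == "j":
                edges = list(S.edges(n, keys=True, data=True))
                if len(edges) != 2:
                    continue  # double edge to the same neighbour; leave
                (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
                a = v1 if u1 == n else u1
                b = v2 if u2 == n else u2
                if a == n or b == n or a == b:
                    continue
                p1 = d1["path"] if d1["path"][-1] == S.nodes[n]["voxel"] else d1["path"][::-1]
                p2 = d2["path"] if d2["path"][0] == S.nodes[n]["voxel"] else d2["path"][::-1]
                S.remove_node(n)
                S.add_edge(a, b, path=p1 + p2[1:], length=d1["length"] + d2["length"])
                changed = True


# ---------------------------------------------------------------------------
# cross-sectional measurement


def _orthonormal_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = tangent / np.linalg.norm(tangent)
    helper = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def measure_segment(
    volume: CTVolume,
    centerline_mm: np.ndarray,
    n_rays: int = 24,
    max_radius_mm: float = 18.0,
    min_contrast_hu: float = 200.0,
    max_wall_mm: float = 5.0,
    max_cross_sections: int = 40,
) -> tuple[float, float, int, str]:
    """Measure mean luminal area (mm^2) and wall thickness (mm) of one branch.

    At cross-sections perpendicular to the smoothed centerline, ``n_rays``
    rays are cast outward.  Along each ray the wall appears as an
    attenuation bump between the dark lumen and the parenchyma; the inner
    edge is placed at the half-maximum crossing between the lumen level
    and the bump peak, the outer edge at the half-maximum crossing back
    down toward the level beyond the bump.  Luminal area is the polygon
    area of the inner-edge radii; wall thickness is the mean inner-to-outer
    distance over rays with a resolvable outer edge.  Cross-sections within
    half a local diameter of either end of the branch (the bifurcations)
    are discarded and the medians of the survivors are returned.

    Returns ``(area, wall, n_cross_sections, quality_flag)``; the flag is
    ``unreliable`` when fewer than 3 cross-sections survive or the wall is
    thinner than one voxel.
    """
    pts = np.asarray(centerline_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("centerline needs at least 3 points")
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)

    # smooth and re-tangent
    if pts.shape[0] >= 5:
        sm = ndimage.uniform_filter1d(pts, size=5, axis=0, mode="nearest")
    else:
        sm = pts
    tangents = np.gradient(sm, axis=0)

    dr = float(spacing.min()) / 4.0
    radii = np.arange(dr, max_radius_mm, dr)
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)

    # subsample cross-sections to a manageable number
    idx = np.arange(sm.shape[0])
    if idx.size > max_cross_sections:
        idx = np.unique(np.linspace(0, sm.shape[0] - 1, max_cross_sections).astype(int))

    areas, walls, inner_means = [], [], []
    arclen = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(sm, axis=0), axis=1))])
    positions = []
    for i in idx:
        c, t = sm[i], tangents[i]
        if np.linalg.norm(t) == 0:
            continue
        u, v = _orthonormal_frame(t)
        dirs = np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v)  # (rays, 3)
        pts_mm = c[None, None, :] + dirs[:, None, :] * radii[None, :, None]
        coords = ((pts_mm - origin) / spacing).reshape(-1, 3).T
        prof = ndimage.map_coordinates(
            volume.values, coords, order=1, mode="nearest"
        ).reshape(n_rays, radii.size)
        lumen_level = float(
            ndimage.map_coordinates(volume.values, ((c - origin) / spacing)[:, None],
                                    order=1, mode="nearest")[0]
        )
        r_in = np.full(n_rays, np.nan)
        r_out = np.full(n_rays, np.nan)
        for k in range(n_rays):
            p = prof[k]
            ipk = int(np.argmax(p))
            peak = p[ipk]
            if peak - lumen_level < min_contrast_hu:
                continue
            half_in = 0.5 * (lumen_level + peak)
            rising = np.nonzero(p[: ipk + 1] >= half_in)[0]
            if rising.size == 0:
                continue
            j = rising[0]
            if j == 0:
                r_in[k] = radii[0]
            else:
                f = (half_in - p[j - 1]) / (p[j] - p[j - 1])
                r_in[k] = radii[j - 1] + f * (radii[j] - radii[j - 1])
            # outer edge: half-way back down toward the far-side level
            tail = p[ipk:]
            far_level = float(tail.min())
            if peak - far_level < min_contrast_hu:
                continue  # no outer contrast (e.g. wall merges into soft tissue)
            half_out = 0.5 * (peak + far_level)
            falling = np.nonzero(tail <= half_out)[0]
            if falling.size == 0:
                continue
            j2 = falling[0]
            if j2 > 0:
                f2 = (tail[j2 - 1] - half_out) / (tail[j2 - 1] - tail[j2])
                cand = radii[ipk + j2 - 1] + f2 * dr
                # an outer edge further than any plausible wall is a distant
                # structure (e.g. a mediastinal lung boundary), not the wall
                if cand - r_in[k] <= max_wall_mm:
                    r_out[k] = cand
        valid_in = np.isfinite(r_in)
        if valid_in.sum() < n_rays * 2 // 3:
            continue
        # area by the radial integral 0.5 * sum(r_i^2) * dtheta — exact for a
        # circle, unlike the inscribed polygon which biases low by sin(t)/t
        # (missing rays filled with the median radius)
        ri = np.where(valid_in, r_in, np.nanmedian(r_in))
        area = (np.pi / n_rays) * float(np.sum(ri**2))
        # median over rays: robust to the minority of rays that run into a
        # neighbouring branch or leave the lung and see no outer edge
        thick = r_out - r_in
        valid_w = np.isfinite(thick)
        wall = float(np.nanmedian(thick[valid_w])) if valid_w.sum() >= n_rays // 3 else np.nan
        areas.append(area)
        walls.append(wall)
        inner_means.append(float(np.nanmean(ri)))
        positions.append(arclen[i])

    if not areas:
        return float("nan"), float("nan"), 0, "unreliable"

    # drop cross-sections within half a diameter of either end (bifurcations)
    diam = 2.0 * float(np.median(inner_means))
    total = arclen[-1]
    keep = [
        j for j, s in enumerate(positions)
        if s >= 0.5 * diam and (total - s) >= 0.5 * diam
    ]
    if len(keep) < 3:
        keep = list(range(len(areas)))  # too short to trim; fall back, flag below
        flag = "unreliable"
    else:
        flag = "ok"
    area = float(np.median([areas[j] for j in keep]))
    wall_vals = [walls[j] for j in keep if np.isfinite(walls[j])]
    wall = float(np.median(wall_vals)) if wall_vals else float("nan")
    if len(keep) < 3:
        flag = "unreliable"
    elif not np.isfinite(wall) or wall < 1.25 * float(spacing.min()):
        # area is trustworthy but the wall is at the resolution floor: a
        # sub-voxel wall blurs to a bump ~1.1 voxels wide, so any estimate
        # below 1.25 voxels is indistinguishable from it.  Also covers a
        # missing outer edge (e.g. a mediastinal trachea with no
        # parenchymal contrast).
        flag = "wall_unreliable" if flag == "ok" else flag
    return area, wall, len(keep), flag


def measure_tree(volume: CTVolume, tree: AirwayTree, **kwargs) -> AirwayTree:
    """Measure every segment of a tree in place and return it."""
    for seg in tree.segments:
        if seg.centerline.shape[0] < 3:
            seg.quality_flag = "unreliable"
            continue
        area, wall, n, flag = measure_segment(volume, seg.centerline, **kwargs)
        seg.mean_lumen_area = area
        seg.mean_wall_thickness = wall
        seg.n_cross_sections = n
        seg.quality_flag = flag
    return tree


# ---------------------------------------------------------------------------
# per-generation summaries and normalizations


def per_generation_summary(
    tree: AirwayTree, max_generation: int = 6, include_unreliable: bool = False
) -> list[GenerationSummary]:
    """Average lumen area and wall thickness across segments per generation.

    Generations beyond ``max_generation`` are dropped; a generation with no
    measurable segment is emitted with ``flag='absent'``.  Averaging is
    segment-mean-then-generation-mean.
    """
    if not tree.segments:
        raise ValueError("empty tree")
    out: list[GenerationSummary] = []
    area_flags = ("ok", "wall_unreliable")  # wall_unreliable: area still valid
    for g in range(1, max_generation + 1):
        segs = [s for s in tree.segments if s.generation == g]
        if not include_unreliable:
            good = [s for s in segs
                    if s.quality_flag in area_flags and np.isfinite(s.mean_lumen_area)]
        else:
            good = [s for s in segs if np.isfinite(s.mean_lumen_area)]
        if not good:
            out.append(GenerationSummary(generation=g, mean_area=float("nan"),
                                         mean_wall=float("nan"), n_segments=0,
                                         flag="absent"))
            continue
        area = float(np.mean([s.mean_lumen_area for s in good]))
        wall_vals = [s.mean_wall_thickness for s in good
                     if s.quality_flag == "ok" and np.isfinite(s.mean_wall_thickness)]
        wall = float(np.mean(wall_vals)) if wall_vals else float("nan")
        out.append(GenerationSummary(generation=g, mean_area=area, mean_wall=wall,
                                     n_segments=len(good)))
    return out


def normalize_to_subject(summary: GenerationSummary, tlc: float) -> GenerationSummary:
    """Normalise a generation summary to a subject: area to TLC (mm^2/L) and
    wall thickness to the same generation's luminal area (mm/mm^2).  A
    wall-to-radius ratio (wall / equivalent circular radius) is computed
    alongside."""
    if tlc <= 0:
        raise ValueError(f"TLC must be positive, got {tlc}")
    if summary.flag == "absent":
        return summary
    if not summary.mean_area > 0:
        raise ValueError(f"generation {summary.generation}: non-positive area")
    radius = float(np.sqrt(summary.mean_area / np.pi))
    return GenerationSummary(
        generation=summary.generation,
        mean_area=summary.mean_area,
        mean_wall=summary.mean_wall,
        n_segments=summary.n_segments,
        area_over_tlc=summary.mean_area / tlc,
        wall_over_area=summary.mean_wall / summary.mean_area,
        wall_over_radius=summary.mean_wall / radius,
        flag=summary.flag,
    )


# ---------------------------------------------------------------------------
# serialization


def tree_to_json(tree: AirwayTree) -> str:
    payload = []
    for s in tree.segments:
        d = asdict(s)
        d["centerline"] = np.asarray(s.centerline).tolist()
        payload.append(d)
    return json.dumps({"segments": payload}, indent=1)


def tree_from_json(text: str) -> AirwayTree:
    data = json.loads(text)
    segs = []
    for d in data["segments"]:
        d["centerline"] = np.asarray(d["centerline"], dtype=float)
        segs.append(AirwaySegment(**d))
    return AirwayTree(segments=segs)
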