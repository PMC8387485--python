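"""Centerline skeletons and their junction/branch graph census.

A thinned skeleton is decomposed into nodes (endpoints and junction
clusters) and branches (slab paths between nodes).  Pixel neighbour count
classifies pixels: endpoint (1 neighbour), slab (2), junction candidate
(>= 3); touching junction candidates merge into a single junction node so
that thick crossings are not over-counted.  Branch length is the weighted
step metric (1, sqrt 2, sqrt 3 for axis/diagonal/3D-diagonal moves).

Junction counts of degree 3 ("triple") and 4 ("quadruple") are the summary
statistics reported per field.
"""

from __future__ import annotations

import itertools
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import apply_hysteresis_threshold
from skimage.morphology import skeletonize as _sk_thin

from .preprocess import ImageStack

__all__ = [
    "SkeletonGraph",
    "SkeletonNode",
    "SkeletonEdge",
    "erode",
    "skeletonize_2d",
    "ridge_detect_3d",
    "build_graph",
    "junction_census",
    "branch_stats",
    "contract_short_branches",
    "prune_spurs",
]

JunctionCensus = namedtuple("JunctionCensus", "total n_triple n_quadruple n_higher")
BranchStats = namedtuple("BranchStats", "n_branches total_length_px mean_length_px")


def erode(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Binary erosion with a cross (city-block) structuring element."""
    mask = np.asarray(mask, dtype=bool)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    return ndimage.binary_erosion(mask, structure=structure, iterations=iterations)


def skeletonize_2d(mask: np.ndarray) -> np.ndarray:
    """Homotopy-preserving thinning of a 2D mask to a 1-px centerline."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("skeletonize_2d expects a 2D mask")
    return _sk_thin(mask)


def ridge_detect_3d(
    stack: ImageStack,
    sigma: float = 1.5,
    low: float = 0.08,
    high: float = 0.20,
) -> np.ndarray:
    """3D curvilinear-centerline extraction via Hessian ridge response.

    The ridge strength at each voxel is the negated middle Hessian
    eigenvalue at scale ``sigma`` (strongly negative across a bright tube,
    near zero along it).  Voxels are kept by hysteresis thresholding at
    ``low``/``high`` fractions of the peak response, then thinned to a
    1-voxel skeleton, which keeps branches that cross in different z-planes
    separate.
    """
    vol = np.asarray(stack.voxels, dtype=np.float64)
    if vol.shape[0] < 3:
        raise ValueError("3D ridge detection needs at least 3 slices")
    if int(4 * sigma) + 1 > vol.shape[0]:
        raise ValueError(f"sigma {sigma} too large for a {vol.shape[0]}-slice stack")
    if not 0 <= low <= high:
        raise ValueError("thresholds must satisfy 0 <= low <= high")
    H = hessian_matrix(vol, sigma=sigma, order="rc", use_gaussian_derivatives=True)
    eigs = hessian_matrix_eigvals(H)  # sorted descending along axis 0
    strength = np.maximum(-eigs[1], 0.0)
    peak = strength.max()
    if peak <= 0:
        return np.zeros(vol.shape, dtype=bool)
    mask = apply_hysteresis_threshold(strength, low * peak, high * peak)
    return _sk_thin(mask)


@dataclass
class SkeletonNode:
    id: int
    type: str  # endpoint | junction | isolated | cycle
    coord: tuple
    pixels: list
    degree: int = 0


@dataclass
class SkeletonEdge:
    u: int
    v: int
    path: list  # slab pixels only; node pixels live on the nodes
    length_px: float


@dataclass
class SkeletonGraph:
    nodes: dict
    edges: list
    shape: tuple
    ndim: int

    def node_pixel_count(self) -> int:
        return sum(len(n.pixels) for n in self.nodes.values())

    def edge_pixel_count(self) -> int:
        return sum(len(e.path) for e in self.edges)

    def degrees(self) -> dict:
        return {nid: n.degree for nid, n in self.nodes.items()}


def _neighbour_offsets(ndim: int):
    return [o for o in itertools.product((-1, 0, 1), repeat=ndim) if any(o)]


def _step(a, b) -> float:
    return float(np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b))))


def is_thinned(skeleton: np.ndarray) -> bool:
    """True if thinning the input again changes nothing."""
    skeleton = np.asarray(skeleton, dtype=bool)
    return bool(np.array_equal(_sk_thin(skeleton), skeleton))


def build_graph(skeleton: np.ndarray, check: bool = True) -> SkeletonGraph:
    """Decompose a thinned skeleton into a node/branch graph.

    Every skeleton pixel ends up in exactly one node pixel set or one
    branch path; isolated cycles become a single anchor node carrying a
    self-loop branch.  Deterministic: pixels are visited in lexicographic
    order.
    """
    sk = np.asarray(skeleton, dtype=bool)
    if sk.ndim not in (2, 3):
        raise ValueError("skeleton must be 2D or 3D")
    if check and not is_thinned(sk):
        raise ValueError("input is not a thinned skeleton (re-thinning changes it)")

    coords = np.argwhere(sk)  # lexicographic order
    n_pix = len(coords)
    if n_pix == 0:
        return SkeletonGraph(nodes={}, edges=[], shape=sk.shape, ndim=sk.ndim)

    # index image: pixel -> row in coords, -1 elsewhere (padded for shifts)
    idx_img = np.full(tuple(s + 2 for s in sk.shape), -1, dtype=np.int64)
    core = tuple(slice(1, 1 + s) for s in sk.shape)
    idx_img[core][sk] = np.arange(n_pix)
    offsets = _neighbour_offsets(sk.ndim)
    nb = np.full((n_pix, len(offsets)), -1, dtype=np.int64)
    steps = np.empty(len(offsets))
    for k, o in enumerate(offsets):
        steps[k] = np.sqrt(sum(oi * oi for oi in o))
        shifted = tuple(slice(1 + oi, 1 + oi + s) for oi, s in zip(o, sk.shape))
        nb[:, k] = idx_img[shifted][sk]
    deg_arr = (nb >= 0).sum(axis=1)

    junction_mask = sk & np.zeros(sk.shape, bool)
    junction_mask[tuple(coords[deg_arr >= 3].T)] = True
    labels, n_clusters = ndimage.label(
        junction_mask, structure=np.ones((3,) * sk.ndim, dtype=bool)
    )
    cluster_of = labels[tuple(coords.T)]  # 0 for non-junction pixels

    nodes: dict[int, SkeletonNode] = {}
    node_of = np.full(n_pix, -1, dtype=np.int64)
    next_id = 0
    for cid in range(1, n_clusters + 1):
        members = np.flatnonzero(cluster_of == cid)
        pix = [tuple(c) for c in coords[members]]
        centroid = coords[members].mean(axis=0)
        rep_i = members[
            np.lexsort((np.linalg.norm(coords[members] - centroid, axis=1),))[0]
        ]
        nodes[next_id] = SkeletonNode(next_id, "junction", tuple(coords[rep_i]), pix)
        node_of[members] = next_id
        next_id += 1
    for i in np.flatnonzero(deg_arr <= 1):
        kind = "endpoint" if deg_arr[i] == 1 else "isolated"
        nodes[next_id] = SkeletonNode(next_id, kind, tuple(coords[i]), [tuple(coords[i])])
        node_of[i] = next_id
        next_id += 1

    slab = deg_arr == 2
    visited = np.zeros(n_pix, dtype=bool)
    edges: list[SkeletonEdge] = []
    seen_direct: set[tuple[int, int]] = set()
    node_pixels = np.flatnonzero(node_of >= 0)

    for p in node_pixels:
        for k in range(len(offsets)):
            q = nb[p, k]
            if q < 0:
                continue
            if slab[q] and not visited[q]:
                path = []
                length = steps[k]
                prev, cur = p, q
                while slab[cur]:
                    visited[cur] = True
                    path.append(tuple(coords[cur]))
                    for kk in range(len(offsets)):
                        r = nb[cur, kk]
                        if r >= 0 and r != prev:
                            break
                    length += steps[kk]
                    prev, cur = cur, r
                edges.append(SkeletonEdge(int(node_of[p]), int(node_of[cur]), path, float(length)))
            elif node_of[q] >= 0 and node_of[q] != node_of[p]:
                key = (min(p, q), max(p, q))
                if key not in seen_direct:
                    seen_direct.add(key)
                    edges.append(
                        SkeletonEdge(int(node_of[p]), int(node_of[q]), [], float(steps[k]))
                    )

    # components made only of slab pixels are pure cycles
    for anchor in np.flatnonzero(slab & ~visited):
        if visited[anchor]:
            continue
        visited[anchor] = True
        nodes[next_id] = SkeletonNode(
            next_id, "cycle", tuple(coords[anchor]), [tuple(coords[anchor])]
        )
        node_of[anchor] = next_id
        path = []
        for k in range(len(offsets)):
            if nb[anchor, k] >= 0:
                break
        length = steps[k]
        prev, cur = anchor, nb[anchor, k]
        while cur != anchor:
            visited[cur] = True
            path.append(tuple(coords[cur]))
            for kk in range(len(offsets)):
                r = nb[cur, kk]
                if r >= 0 and r != prev:
                    break
            length += steps[kk]
            prev, cur = cur, r
        edges.append(SkeletonEdge(next_id, next_id, path, float(length)))
        next_id += 1

    for e in edges:
        nodes[e.u].degree += 1
        nodes[e.v].degree += 1  # self-loops count twice by visiting both ends

    return SkeletonGraph(nodes=nodes, edges=edges, shape=sk.shape, ndim=sk.ndim)


def junction_census(graph: SkeletonGraph) -> JunctionCensus:
    """Count junction nodes by degree: triple (3), quadruple (4), higher."""
    n3 = n4 = nh = 0
    for n in graph.nodes.values():
        if n.degree == 3:
            n3 += 1
        elif n.degree == 4:
            n4 += 1
        elif n.degree >= 5:
            nh += 1
    return JunctionCensus(n3 + n4 + nh, n3, n4, nh)


def branch_stats(graph: SkeletonGraph) -> BranchStats:
    """Branch count, total and mean branch length (weighted pixel steps)."""
    n = len(graph.edges)
    total = float(sum(e.length_px for e in graph.edges))
    mean = total / n if n else float("nan")
    return BranchStats(n, total, mean)


def contract_short_branches(graph: SkeletonGraph, max_length: float = 2.0) -> SkeletonGraph:
    """Merge junction pairs linked by branches shorter than ``max_length``.

    Thinning splits one thick crossing into nearby junction clusters joined
    by stub branches of roughly the fibre width; contracting those stubs
    restores the single higher-degree junction.  Node pixel sets absorb the
    contracted stub paths, so pixel coverage is preserved.
    """
    parent = {nid: nid for nid in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    contracted = []
    for e in graph.edges:
        if (
            e.u != e.v
            and e.length_px <= max_length
            and graph.nodes[e.u].type == "junction"
            and graph.nodes[e.v].type == "junction"
        ):
            ru, rv = find(e.u), find(e.v)
            if ru != rv:
                parent[rv] = ru
            contracted.append(e)
    contracted_ids = {id(e) for e in contracted}

    new_nodes: dict[int, SkeletonNode] = {}
    for nid, n in graph.nodes.items():
        r = find(nid)
        if r not in new_nodes:
            new_nodes[r] = SkeletonNode(r, n.type, n.coord, [], 0)
        new_nodes[r].pixels.extend(n.pixels)
    for e in contracted:
        new_nodes[find(e.u)].pixels.extend(e.path)

    new_edges = []
    for e in graph.edges:
        if id(e) in contracted_ids:
            continue
        new_edges.append(SkeletonEdge(find(e.u), find(e.v), list(e.path), e.length_px))
    for n in new_nodes.values():
        n.degree = 0
    for e in new_edges:
        new_nodes[e.u].degree += 1
        new_nodes[e.v].degree += 1
    return SkeletonGraph(new_nodes, new_edges, graph.shape, graph.ndim)


def drop_small_components(graph: SkeletonGraph, min_total_length: float = 0.0) -> SkeletonGraph:
    """Remove connected components whose total branch length is below
    ``min_total_length`` px.

    Free-standing skeleton specks — noise islands, or the short fragment a
    lone soma cluster thins down to — are not fibre branches; any component
    carrying real fibre is far longer than this threshold.
    """
    if min_total_length <= 0:
        return graph
    parent = {nid: nid for nid in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in graph.edges:
        ru, rv = find(e.u), find(e.v)
        if ru != rv:
            parent[rv] = ru
    comp_len: dict[int, float] = {}
    for e in graph.edges:
        r = find(e.u)
        comp_len[r] = comp_len.get(r, 0.0) + e.length_px
    keep_comp = {r for r, ln in comp_len.items() if ln >= min_total_length}
    nodes = {
        nid: SkeletonNode(n.id, n.type, n.coord, list(n.pixels), 0)
        for nid, n in graph.nodes.items()
        if find(nid) in keep_comp
    }
    edges = [
        SkeletonEdge(e.u, e.v, list(e.path), e.length_px)
        for e in graph.edges
        if find(e.u) in keep_comp
    ]
    for e in edges:
        nodes[e.u].degree += 1
        nodes[e.v].degree += 1
    return SkeletonGraph(nodes, edges, graph.shape, graph.ndim)


def prune_spurs(graph: SkeletonGraph, min_length: float = 0.0) -> SkeletonGraph:
    """Drop terminal branches shorter than ``min_length`` and dissolve any
    junction thereby reduced to a pass-through (degree 2).

    Short endpoint spurs are thinning artefacts of rough mask boundaries;
    real terminal fibres are much longer than the fibre width.  Applied
    iteratively until stable.
    """
    if min_length <= 0:
        return graph
    nodes = {nid: SkeletonNode(n.id, n.type, n.coord, list(n.pixels), n.degree)
             for nid, n in graph.nodes.items()}
    edges = [SkeletonEdge(e.u, e.v, list(e.path), e.length_px) for e in graph.edges]

    for _ in range(10):
        changed = False
        # prune endpoint spurs hanging off junctions
        keep = []
        for e in edges:
            tu, tv = nodes[e.u].type, nodes[e.v].type
            spur = (
                e.u != e.v
                and e.length_px < min_length
                and (
                    (tu == "endpoint" and nodes[e.v].degree >= 3)
                    or (tv == "endpoint" and nodes[e.u].degree >= 3)
                )
            )
            if spur:
                nodes[e.u].degree -= 1
                nodes[e.v].degree -= 1
                changed = True
            else:
                keep.append(e)
        edges = keep
        for nid in [nid for nid, n in list(nodes.items())
                    if n.type == "endpoint" and n.degree == 0]:
            nodes.pop(nid)
        # dissolve junctions that dropped to degree 2
        for nid in [n.id for n in list(nodes.values()) if n.type == "junction" and n.degree == 2]:
            if nid not in nodes:
                continue
            inc = [e for e in edges if nid in (e.u, e.v) and e.u != e.v]
            if len(inc) != 2:
                continue
            e1, e2 = inc
            u = e1.v if e1.u == nid else e1.u
            w = e2.v if e2.u == nid else e2.u
            merged = SkeletonEdge(
                u, w, e1.path + nodes[nid].pixels + e2.path, e1.length_px + e2.length_px
            )
            drop = {id(e1), id(e2)}
            edges = [e for e in edges if id(e) not in drop] + [merged]
            nodes.pop(nid)
            changed = True
        if not changed:
            break

    for n in nodes.values():
        n.degree = 0
    for e in edges:
        nodes[e.u].degree += 1
        nodes[e.v].degree += 1
    return SkeletonGraph(nodes, edges, graph.shape, graph.ndim)
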