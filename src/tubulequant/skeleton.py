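"""Skeletonisation and skeleton-graph branch measurement.

A cleaned binary image is thinned to unit-width curves, then decomposed
into a graph: nodes are endpoints (exactly 1 skeleton neighbour under
8-connectivity), junctions (>= 3 neighbours; mutually adjacent junction
pixels merge into one junction node) and isolated pixels; branches are
the pixel paths between nodes. Each branch is measured by its geodesic
length — 1 per axial step, sqrt(2) per diagonal step — so a straight
run of n pixels measures n - 1. This branch table is the unit on which
tubule classification operates.

Short spurs emanating from junctions (thinning artifacts, typically
1-2 px) are pruned before measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .io_formats import BranchRecord

__all__ = [
    "SkeletonGraph",
    "SkeletonComponent",
    "Branch",
    "NonThinSkeletonError",
    "skeletonize",
    "analyze_skeleton",
]

SQRT2 = math.sqrt(2.0)

_N8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_STRUCT8 = np.ones((3, 3), dtype=bool)


class NonThinSkeletonError(ValueError):
    """Raised when analyze_skeleton is given a non-unit-width image."""


@dataclass(frozen=True)
class Branch:
    """A skeleton path between two nodes (possibly a closed loop).

    ``path`` lists the pixels in traversal order, including both end
    pixels. ``length_px`` is the geodesic length ``n_axial + n_diag*sqrt(2)``.
    """

    component_id: int
    branch_id: int
    path: tuple[tuple[int, int], ...]
    n_axial: int
    n_diag: int
    n_junction_contacts: int
    is_loop: bool = False

    @property
    def length_px(self) -> float:
        return self.n_axial + self.n_diag * SQRT2

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.path[0], self.path[-1])


@dataclass(frozen=True)
class SkeletonComponent:
    """One 8-connected skeleton component and its measured branches.

    ``junctions`` holds one representative pixel per merged junction
    node; ``junction_pixels`` holds every pixel with >= 3 neighbours.
    """

    component_id: int
    pixels: frozenset[tuple[int, int]]
    branches: tuple[Branch, ...]
    endpoints: tuple[tuple[int, int], ...]
    junctions: tuple[tuple[int, int], ...]
    junction_pixels: frozenset[tuple[int, int]]
    max_path_length_px: float

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class SkeletonGraph:
    """The measured skeleton of one image."""

    shape: tuple[int, int]
    components: tuple[SkeletonComponent, ...]

    @property
    def branches(self) -> list[Branch]:
        return [b for comp in self.components for b in comp.branches]

    def branch_lengths(self) -> list[float]:
        return [b.length_px for b in self.branches]

    def component_max_path_lengths(self) -> list[float]:
        return [c.max_path_length_px for c in self.components]

    def to_branch_records(self, image_id: str) -> list[BranchRecord]:
        return [
            BranchRecord(
                image_id=image_id,
                component_id=b.component_id,
                branch_id=b.branch_id,
                length_px=b.length_px,
                endpoints=b.endpoints,
                n_junction_contacts=b.n_junction_contacts,
            )
            for b in self.branches
        ]


def skeletonize(binary: np.ndarray) -> np.ndarray:
    """Thin a binary image to unit-width curves (topology preserving).

    Output pixels are a subset of the input and the number of
    8-connected components is preserved.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 2:
        raise ValueError("binary image must be 2-D")
    if not binary.any():
        return np.zeros_like(binary)
    return _sk_skeletonize(binary)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    return ndimage.convolve(
        skel.astype(np.uint8), kernel, mode="constant", cval=0
    ) * skel


def _neighbors_of(pix: tuple[int, int], skel: np.ndarray) -> list[tuple[int, int]]:
    r, c = pix
    h, w = skel.shape
    out = []
    for dr, dc in _N8:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
            out.append((rr, cc))
    return out


def _trace_component(
    comp_pixels: list[tuple[int, int]],
    skel: np.ndarray,
    ncount: np.ndarray,
    component_id: int,
) -> SkeletonComponent:
    """Decompose one connected component into branches.

    Node pixels have neighbour count != 2. Junction pixels that touch
    each other collapse into a single junction node (thinning leaves
    small junction clusters); edges internal to a cluster are not
    branches. Pure cycles (all degree-2) become one closed-loop branch.
    """
    pixset = set(comp_pixels)
    node_pixels = sorted(p for p in comp_pixels if ncount[p] != 2)
    junction_pixels = {p for p in node_pixels if ncount[p] >= 3}
    endpoints = tuple(p for p in node_pixels if ncount[p] == 1)

    # merge mutually adjacent junction pixels into clusters
    cluster_of: dict[tuple[int, int], int] = {}
    clusters: list[list[tuple[int, int]]] = []
    for p in sorted(junction_pixels):
        if p in cluster_of:
            continue
        idx = len(clusters)
        members = [p]
        cluster_of[p] = idx
        stack = [p]
        while stack:
            q = stack.pop()
            for nb in _neighbors_of(q, skel):
                if nb in junction_pixels and nb not in cluster_of:
                    cluster_of[nb] = idx
                    members.append(nb)
                    stack.append(nb)
        clusters.append(members)

    def node_key(p: tuple[int, int]):
        return ("J", cluster_of[p]) if p in junction_pixels else ("P", p)

    visited_edges: set[frozenset[tuple[int, int]]] = set()
    interior_used: set[tuple[int, int]] = set()
    branches: list[Branch] = []

    def walk(start, first) -> list[tuple[int, int]] | None:
        """Walk start->first through degree-2 pixels to the next node pixel."""
        edge = frozenset((start, first))
        if edge in visited_edges:
            return None
        visited_edges.add(edge)
        path = [start, first]
        prev, cur = start, first
        while ncount[cur] == 2 and cur != start:
            interior_used.add(cur)
            nbrs = [n for n in _neighbors_of(cur, skel) if n != prev]
            if not nbrs:  # pragma: no cover - degree-2 guarantees a successor
                break
            nxt = nbrs[0]
            visited_edges.add(frozenset((cur, nxt)))
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    def add_branch(path: list[tuple[int, int]]) -> None:
        n_axial = n_diag = 0
        for a, b in zip(path, path[1:]):
            if a[0] != b[0] and a[1] != b[1]:
                n_diag += 1
            else:
                n_axial += 1
        contacts = sum(
            1 for end in (path[0], path[-1]) if end in junction_pixels
        )
        loop = len(path) > 2 and (
            path[0] == path[-1]
            or (
                path[0] in junction_pixels
                and path[-1] in junction_pixels
                and cluster_of[path[0]] == cluster_of[path[-1]]
            )
        )
        branches.append(
            Branch(
                component_id=component_id,
                branch_id=len(branches),
                path=tuple(path),
                n_axial=n_axial,
                n_diag=n_diag,
                n_junction_contacts=contacts,
                is_loop=loop,
            )
        )

    # branches emanating from node pixels, deterministic scan order
    for node in node_pixels:
        for nbr in _neighbors_of(node, skel):
            if (
                node in junction_pixels
                and nbr in junction_pixels
                and cluster_of[node] == cluster_of[nbr]
            ):
                continue  # edge internal to a junction cluster
            path = walk(node, nbr)
            if path is not None:
                add_branch(path)

    # pure cycles: degree-2 pixels not reached from any node
    remaining = sorted(pixset - interior_used - set(node_pixels))
    for start in remaining:
        if start in interior_used:
            continue
        nbrs = _neighbors_of(start, skel)
        path = walk(start, nbrs[0])
        if path is not None:
            interior_used.add(start)
            add_branch(path)

    max_len = _max_geodesic_path(node_key, node_pixels, branches)
    return SkeletonComponent(
        component_id=component_id,
        pixels=frozenset(pixset),
        branches=tuple(branches),
        endpoints=endpoints,
        junctions=tuple(min(members) for members in clusters),
        junction_pixels=frozenset(junction_pixels),
        max_path_length_px=max_len,
    )


def _max_geodesic_path(node_key, node_pixels, branches) -> float:
    """Longest shortest-path between nodes (the component's 'diameter').

    Falls back to the longest single branch for node-free cycles.
    """
    if not branches:
        return 0.0
    g = nx.MultiGraph()
    for p in node_pixels:
        g.add_node(node_key(p))
    for b in branches:
        g.add_edge(node_key(b.path[0]), node_key(b.path[-1]), weight=b.length_px)
    best = max(b.length_px for b in branches)
    nodes = list(g.nodes)
    if len(nodes) >= 2:
        lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        for i, u in enumerate(nodes):
            du = lengths.get(u, {})
            for v in nodes[i + 1 :]:
                d = du.get(v)
                if d is not None and d > best:
                    best = d
    return best


def _prune_spurs(skel: np.ndarray, graph: SkeletonGraph, prune_px: float) -> np.ndarray:
    """Remove endpoint->junction spur branches shorter than prune_px."""
    out = skel.copy()
    changed = False
    for comp in graph.components:
        junctions = comp.junction_pixels
        for b in comp.branches:
            if b.is_loop or b.length_px >= prune_px:
                continue
            ends = (b.path[0], b.path[-1])
            # spur: exactly one end at a junction, the other free
            if sum(e in junctions for e in ends) != 1:
                continue
            for p in b.path:
                if p not in junctions:
                    out[p] = False
                    changed = True
    return out if changed else skel


def analyze_skeleton(skeleton: np.ndarray, prune_px: float = 2.0) -> SkeletonGraph:
    """Trace and measure every branch of a unit-width skeleton.

    Parameters
    ----------
    skeleton :
        Boolean unit-width skeleton (output of :func:`skeletonize`).
    prune_px :
        Branches shorter than this that dangle off a junction are
        removed before measurement (thinning-artifact spurs). 0 disables.

    Raises
    ------
    NonThinSkeletonError
        If any pixel has a fully-foreground 3x3 neighbourhood (i.e. the
        input is not thin).
    """
    skel = np.asarray(skeleton, dtype=bool)
    if skel.ndim != 2:
        raise ValueError("skeleton must be a 2-D boolean grid")
    ncount = _neighbor_counts(skel)
    if (ncount == 8).any():
        r, c = np.argwhere(ncount == 8)[0]
        raise NonThinSkeletonError(
            f"input is not unit-width: pixel ({r}, {c}) has a solid 3x3 "
            "neighbourhood; run skeletonize first"
        )

    graph = _trace(skel, ncount)
    if prune_px > 0:
        pruned = _prune_spurs(skel, graph, prune_px)
        if pruned is not skel:
            # re-thin: removing a spur can leave its junction-cluster
            # pixel protruding from an otherwise straight run
            pruned = skeletonize(pruned)
            graph = _trace(pruned, _neighbor_counts(pruned))
    return graph


def _trace(skel: np.ndarray, ncount: np.ndarray) -> SkeletonGraph:
    labels, n_comp = ndimage.label(skel, structure=_STRUCT8)
    components = []
    if n_comp:
        objects = ndimage.find_objects(labels)
        for cid in range(1, n_comp + 1):
            sl = objects[cid - 1]
            rows, cols = np.nonzero(labels[sl] == cid)
            pix = [
                (int(r + sl[0].start), int(c + sl[1].start))
                for r, c in zip(rows, cols)
            ]
            components.append(_trace_component(pix, skel, ncount, cid))
    return SkeletonGraph(shape=skel.shape, components=tuple(components))
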