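"""Skeletonization, diameter mapping, and vessel-graph topology.

A binary vessel mask is thinned to one-pixel-wide centerlines, per-pixel
vessel diameters are read off the Euclidean distance transform of the mask
(diameter = 2 x EDT at the centerline), and the skeleton is converted into
a graph whose nodes are branch points (>= 3 skeleton neighbours,
8-connectivity; adjacent branch pixels merged into one node) and endpoints
(exactly 1 neighbour).  Segments are the degree-2 pixel chains between
nodes; their length is the sum of inter-pixel steps (1 orthogonal, sqrt(2)
diagonal) times the pixel size.

Spurious short terminal branches ("twigs") and isolated specks are pruned:
endpoint-terminated segments shorter than the twig threshold (in pixels)
and connected components whose total length falls below it are removed,
after which any branch node left with exactly two incident segments is
dissolved by merging them.  Pruning is a single pass by default; it can be
iterated to a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageSpec

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonMap:
    """One-pixel-wide centerline raster derived from a vessel mask."""

    skeleton: np.ndarray
    mask: np.ndarray | None = None


@dataclass
class DiameterMap:
    """Per-skeleton-pixel vessel diameter (NaN off the skeleton)."""

    diameters_px: np.ndarray
    skeleton: np.ndarray
    spec: ImageSpec

    @property
    def skeleton_diameters_px(self) -> np.ndarray:
        return self.diameters_px[self.skeleton]

    @property
    def skeleton_diameters_um(self) -> np.ndarray:
        return self.skeleton_diameters_px * self.spec.pixel_size_um


@dataclass
class GraphNode:
    """A branch-point cluster, endpoint, or isolated pixel."""

    id: int
    pixels: list[tuple[int, int]]
    kind: str  # 'branch' | 'endpoint' | 'isolate'

    @property
    def centroid(self) -> tuple[int, int]:
        arr = np.asarray(self.pixels)
        r, c = arr.mean(axis=0)
        return int(round(r)), int(round(c))


@dataclass
class GraphSegment:
    """A centerline chain between two nodes (or a closed cycle)."""

    id: int
    node_ids: tuple[int | None, int | None]
    chain: list[tuple[int, int]]  # includes terminal node pixels
    length_px: float
    mean_diameter_um: float = float("nan")

    def length_um(self, spec: ImageSpec) -> float:
        return self.length_px * spec.pixel_size_um

    @property
    def interior_count(self) -> int:
        n = len(self.chain)
        if self.node_ids == (None, None):  # cycle: all pixels interior
            return n
        return max(n - sum(nid is not None for nid in self.node_ids), 0)


@dataclass
class VesselGraph:
    """Pruned or unpruned skeleton topology."""

    nodes: dict[int, GraphNode]
    segments: list[GraphSegment]
    spec: ImageSpec
    skeleton_px_count: int = 0
    pruned: bool = False

    def degree(self, node_id: int) -> int:
        return sum(
            (seg.node_ids[0] == node_id) + (seg.node_ids[1] == node_id)
            for seg in self.segments
        )

    @property
    def branch_nodes(self) -> list[GraphNode]:
        return [n for n in self.nodes.values() if n.kind == "branch"]

    @property
    def endpoints(self) -> list[GraphNode]:
        return [n for n in self.nodes.values() if n.kind == "endpoint"]

    @property
    def n_branch_nodes(self) -> int:
        return len(self.branch_nodes)

    def segment_lengths_um(self) -> np.ndarray:
        return np.array([s.length_um(self.spec) for s in self.segments])

    @property
    def total_length_mm(self) -> float:
        return float(self.segment_lengths_um().sum() / 1000.0)

    def to_edgelist(self):
        """Edge list as a pandas DataFrame (lengths in um)."""
        import pandas as pd

        rows = [
            {
                "segment_id": s.id,
                "node_u": s.node_ids[0],
                "node_v": s.node_ids[1],
                "length_um": s.length_um(self.spec),
                "mean_diameter_um": s.mean_diameter_um,
                "n_pixels": len(s.chain),
            }
            for s in self.segments
        ]
        return pd.DataFrame(
            rows,
            columns=["segment_id", "node_u", "node_v", "length_um",
                     "mean_diameter_um", "n_pixels"],
        )

    def to_networkx(self):
        """MultiGraph view (GraphML-exportable); cycles get synthetic nodes."""
        import networkx as nx

        g = nx.MultiGraph()
        for nid, node in self.nodes.items():
            g.add_node(nid, kind=node.kind, row=node.centroid[0], col=node.centroid[1])
        synthetic = -1
        for s in self.segments:
            u, v = s.node_ids
            if u is None and v is None:
                r, c = s.chain[0]
                g.add_node(synthetic, kind="cycle", row=int(r), col=int(c))
                u = v = synthetic
                synthetic -= 1
            g.add_edge(u, v, key=s.id, length_um=s.length_um(self.spec),
                       mean_diameter_um=float(s.mean_diameter_um))
        return g


# ---------------------------------------------------------------------------
# skeletonization and diameters
# ---------------------------------------------------------------------------

def skeletonize(mask) -> SkeletonMap:
    """Homotopic thinning of a binary mask to 1-px-wide centerlines."""
    from skimage.morphology import skeletonize as _sk

    arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not arr.any():
        return SkeletonMap(np.zeros_like(arr), arr)
    return SkeletonMap(_sk(arr), arr)


def diameter_map(mask, skeleton: SkeletonMap | np.ndarray, spec: ImageSpec) -> DiameterMap:
    """Diameter = 2 x Euclidean distance transform of the mask, sampled on
    the skeleton.  Raises if any skeleton pixel falls outside the mask."""
    arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    skel = np.asarray(getattr(skeleton, "skeleton", skeleton), dtype=bool)
    if (skel & ~arr).any():
        raise ValueError("skeleton pixel outside mask")
    edt = ndimage.distance_transform_edt(arr)
    diam = np.full(arr.shape, np.nan)
    diam[skel] = 2.0 * edt[skel]
    return DiameterMap(diameters_px=diam, skeleton=skel, spec=spec)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def build_graph(
    skeleton: SkeletonMap | np.ndarray,
    diameters: DiameterMap | None = None,
    spec: ImageSpec | None = None,
) -> VesselGraph:
    """Convert a skeleton raster into a node/segment graph.

    Branch pixels (>= 3 neighbours) merge into single nodes by 8-connected
    clustering; endpoints and isolated pixels are single-pixel nodes.
    Closed loops without any node become node-less cycle segments.
    """
    skel = np.asarray(getattr(skeleton, "skeleton", skeleton), dtype=bool)
    spec = spec or ImageSpec(width_px=skel.shape[1], height_px=skel.shape[0])
    counts = _neighbor_counts(skel) * skel
    branch = skel & (counts >= 3)
    endpoint = skel & (counts == 1)
    isolate = skel & (counts == 0)

    nodes: dict[int, GraphNode] = {}
    node_of_pixel: dict[tuple[int, int], int] = {}
    next_id = 0

    labels, n_clusters = ndimage.label(branch, structure=np.ones((3, 3)))
    for lab in range(1, n_clusters + 1):
        pix = [tuple(p) for p in np.argwhere(labels == lab)]
        nodes[next_id] = GraphNode(next_id, pix, "branch")
        for p in pix:
            node_of_pixel[p] = next_id
        next_id += 1
    for kind, grid in (("endpoint", endpoint), ("isolate", isolate)):
        for p in map(tuple, np.argwhere(grid)):
            nodes[next_id] = GraphNode(next_id, [p], kind)
            node_of_pixel[p] = next_id
            next_id += 1

    skel_set = {tuple(p) for p in np.argwhere(skel)}
    dmap = None
    if diameters is not None:
        dmap = diameters.diameters_px

    def nbrs(p):
        r, c = p
        return [(r + dr, c + dc) for dr, dc in _NEIGHBORS if (r + dr, c + dc) in skel_set]

    def step(p, q) -> float:
        return float(np.hypot(p[0] - q[0], p[1] - q[1]))

    def chain_length(chain) -> float:
        return sum(step(chain[i], chain[i + 1]) for i in range(len(chain) - 1))

    def make_segment(chain, u, v, seg_id) -> GraphSegment:
        md = float("nan")
        if dmap is not None and chain:
            vals = [dmap[p] for p in chain if np.isfinite(dmap[p])]
            if vals:
                md = float(np.mean(vals)) * spec.pixel_size_um
        return GraphSegment(seg_id, (u, v), list(chain), chain_length(chain), md)

    segments: list[GraphSegment] = []
    visited_interior: set[tuple[int, int]] = set()
    seen_direct: set[frozenset] = set()
    seg_id = 0
    node_pixels = set(node_of_pixel)

    for nid, node in nodes.items():
        for p in node.pixels:
            for q in nbrs(p):
                if q in node_pixels:
                    other = node_of_pixel[q]
                    if other == nid and q in node.pixels:
                        continue  # intra-cluster adjacency
                    key = frozenset((p, q))
                    if key in seen_direct:
                        continue
                    seen_direct.add(key)
                    segments.append(make_segment([p, q], nid, other, seg_id))
                    seg_id += 1
                    continue
                if q in visited_interior:
                    continue
                # walk the degree-2 chain until the next node pixel
                chain = [p, q]
                visited_interior.add(q)
                prev, cur = p, q
                while True:
                    nxt = [t for t in nbrs(cur) if t != prev]
                    # prefer continuing to a node pixel; otherwise the
                    # unique unvisited interior neighbour
                    node_next = [t for t in nxt if t in node_pixels]
                    if node_next:
                        end = node_next[0]
                        chain.append(end)
                        segments.append(make_segment(chain, nid, node_of_pixel[end], seg_id))
                        seg_id += 1
                        break
                    free = [t for t in nxt if t not in visited_interior]
                    if not free:
                        # dead end without an endpoint marker (cannot occur
                        # on a clean 1-px skeleton, but keep it total)
                        segments.append(make_segment(chain, nid, None, seg_id))
                        seg_id += 1
                        break
                    prev, cur = cur, free[0]
                    chain.append(cur)
                    visited_interior.add(cur)

    # remaining pixels belong to pure cycles (all degree 2)
    remaining = skel_set - node_pixels - visited_interior
    while remaining:
        start = min(remaining)
        chain = [start]
        remaining.discard(start)
        prev, cur = None, start
        while True:
            nxt = [t for t in nbrs(cur) if t != prev and t in remaining]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            chain.append(cur)
            remaining.discard(cur)
        length = chain_length(chain) + (step(chain[-1], chain[0]) if len(chain) > 2 else 0.0)
        seg = make_segment(chain, None, None, seg_id)
        seg.length_px = length
        segments.append(seg)
        seg_id += 1

    return VesselGraph(
        nodes=nodes, segments=segments, spec=spec,
        skeleton_px_count=int(skel.sum()), pruned=False,
    )


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _components(graph: VesselGraph) -> list[tuple[set[int], list[GraphSegment]]]:
    """Connected components as (node-id set, segment list) pairs."""
    parent: dict = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for nid in graph.nodes:
        parent.setdefault(nid, nid)
    for seg in graph.segments:
        u, v = seg.node_ids
        tag = ("seg", seg.id)
        parent.setdefault(tag, tag)
        for t in (u, v):
            if t is not None:
                parent.setdefault(t, t)
                union(tag, t)
    groups: dict = {}
    for nid in graph.nodes:
        groups.setdefault(find(nid), (set(), []))[0].add(nid)
    for seg in graph.segments:
        groups.setdefault(find(("seg", seg.id)), (set(), []))[1].append(seg)
    return list(groups.values())


def prune_graph(graph: VesselGraph, twig_px: float = 2.0, iterate: bool = False) -> VesselGraph:
    """Remove twigs and isolated specks; dissolve resulting degree-2 nodes.

    A twig is an endpoint-terminated segment with path length strictly
    below ``twig_px`` pixels; a speck is a connected component whose total
    length is below ``twig_px``.  With ``iterate=True`` the pass repeats
    until no twig remains.
    """
    nodes = {nid: n for nid, n in graph.nodes.items()}
    segments = list(graph.segments)

    while True:
        g = VesselGraph(nodes, segments, graph.spec, graph.skeleton_px_count, True)

        def is_endpoint_node(nid):
            return nid is not None and nodes[nid].kind in ("endpoint", "isolate")

        drop_ids = {
            s.id for s in segments
            if s.length_px < twig_px
            and (is_endpoint_node(s.node_ids[0]) or is_endpoint_node(s.node_ids[1]))
        }
        # isolated structures below the length threshold
        for node_set, comp_segs in _components(g):
            if sum(s.length_px for s in comp_segs) < twig_px:
                drop_ids.update(s.id for s in comp_segs)
                for nid in node_set:
                    nodes.pop(nid, None)
        n_dropped = len(drop_ids)
        segments = [s for s in segments if s.id not in drop_ids]

        # drop now-disconnected endpoint/isolate nodes
        incident: dict[int, list[GraphSegment]] = {}
        for s in segments:
            for nid in s.node_ids:
                if nid is not None:
                    incident.setdefault(nid, []).append(s)
        for nid in list(nodes):
            if nid not in incident and nodes[nid].kind != "isolate":
                nodes.pop(nid, None)
            elif nid not in incident:
                nodes.pop(nid, None)

        # dissolve degree-2 branch nodes by merging their two segments
        changed = True
        while changed:
            changed = False
            incident = {}
            for s in segments:
                for nid in s.node_ids:
                    if nid is not None:
                        incident.setdefault(nid, []).append(s)
            for nid, segs in incident.items():
                if nodes.get(nid) is None or nodes[nid].kind != "branch":
                    continue
                ends = sum((s.node_ids[0] == nid) + (s.node_ids[1] == nid) for s in segs)
                if ends != 2 or len(segs) != 2:
                    continue
                s1, s2 = segs
                c1 = list(s1.chain)
                if s1.node_ids[0] == nid:
                    c1.reverse()
                    u = s1.node_ids[1]
                else:
                    u = s1.node_ids[0]
                c2 = list(s2.chain)
                if s2.node_ids[0] == nid:
                    v = s2.node_ids[1]
                else:
                    v = s2.node_ids[0]
                    c2.reverse()
                # c1 ends at a pixel of cluster nid, c2 starts at one
                joint = float(np.hypot(c1[-1][0] - c2[0][0], c1[-1][1] - c2[0][1]))
                if c1[-1] == c2[0]:
                    joint = 0.0
                    c2 = c2[1:]
                dvals = [d for d in (s1.mean_diameter_um, s2.mean_diameter_um)
                         if np.isfinite(d)]
                merged = GraphSegment(
                    id=s1.id, node_ids=(u, v), chain=c1 + c2,
                    length_px=s1.length_px + s2.length_px + joint,
                    mean_diameter_um=float(np.mean(dvals)) if dvals else float("nan"),
                )
                segments = [s for s in segments if s.id not in (s1.id, s2.id)]
                segments.append(merged)
                nodes.pop(nid, None)
                changed = True
                break

        if not iterate or n_dropped == 0:
            break

    return VesselGraph(
        nodes=nodes, segments=segments, spec=graph.spec,
        skeleton_px_count=graph.skeleton_px_count, pruned=True,
    )
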