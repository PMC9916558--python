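"""Explant micrograph → binary mask → skeleton graph → outgrowth metrics.

The chain is: adaptive (local-mean) thresholding of the neuronal-marker
channel (:func:`preprocess`), delineation of the explant body as the
largest dense region (:func:`segment_body`), skeletonization of the
outgrowth outside the body and conversion of the skeleton into a spatial
graph (:func:`skeletonize_to_graph`), suppression of short skeleton spurs
(:func:`prune_graph`), and derivation of per-explant morphometry
(:func:`extract_metrics`): numbers of endings, branch points and start
points, per-ending root-to-tip lengths, total outgrowth length, and the
projected body area.

Conventions: 0-based (row, col) pixel coordinates, origin top-left;
8-connectivity everywhere; a diagonal skeleton step costs
sqrt(2) × pixel_size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import closing, dilation, disk, opening, skeletonize

__all__ = [
    "ExplantBody",
    "SkeletonGraph",
    "OutgrowthMetrics",
    "preprocess",
    "segment_body",
    "skeletonize_to_graph",
    "prune_graph",
    "extract_metrics",
    "analyze_image",
]

_SQRT2 = float(np.sqrt(2.0))
_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExplantBody:
    mask: np.ndarray
    centroid: tuple[float, float]
    projected_area_um2: float
    pixel_size_um: float


@dataclass
class OutgrowthMetrics:
    """Per-explant morphometry. ``median_length_um`` is None (missing, never
    0) when there are no endings. ``endings`` is a per-ending table with
    columns ``r, c, start_id, start_r, start_c, length_um,
    graph_length_um, disconnected``."""

    n_endings: int
    n_branch_points: int
    n_start_points: int
    lengths_um: np.ndarray
    median_length_um: Optional[float]
    longest_um: Optional[float]
    total_length_um: float
    projected_area_um2: Optional[float]
    endings: pd.DataFrame = field(default_factory=pd.DataFrame)


class SkeletonGraph:
    """Spatial graph of the skeletonized outgrowth.

    Wraps a :class:`networkx.MultiGraph`; nodes carry ``rc`` (float
    centroid), ``pixels`` and ``role`` (ending / branch / start /
    passthrough), edges carry the traced pixel ``path`` (ordered from the
    ``u`` side) and ``length_um`` (chain-code length, diagonal steps
    sqrt(2) × pixel_size).
    """

    def __init__(self, graph: nx.MultiGraph, pixel_size_um: float):
        self.g = graph
        self.pixel_size_um = pixel_size_um
        self._assign_roles()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        nodes: dict[int, tuple[float, float]],
        edges: list[tuple[int, int, float]],
        start_ids: set[int] = frozenset(),
        pixel_size_um: float = 1.0,
    ) -> "SkeletonGraph":
        """Build directly from node coordinates and (u, v, length_um)
        edges — mainly for constructed fixtures and file round-trips."""
        g = nx.MultiGraph()
        for nid, rc in nodes.items():
            g.add_node(nid, rc=(float(rc[0]), float(rc[1])), pixels=[tuple(rc)],
                       start=nid in start_ids)
        for u, v, length in edges:
            # no pixel trace: lengths are taken as declared
            g.add_edge(u, v, path=None, length_um=float(length))
        return cls(g, pixel_size_um)

    def _assign_roles(self) -> None:
        for n in self.g.nodes:
            if self.g.nodes[n].get("start", False):
                self.g.nodes[n]["role"] = "start"
            else:
                deg = self.g.degree(n)
                role = "ending" if deg <= 1 else ("branch" if deg >= 3 else "passthrough")
                self.g.nodes[n]["role"] = role

    # -- queries -------------------------------------------------------------

    def nodes_with_role(self, role: str) -> list:
        return [n for n, d in self.g.nodes(data=True) if d["role"] == role]

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def total_length_um(self) -> float:
        return float(sum(d["length_um"] for *_, d in self.g.edges(data=True)))

    def oriented_path(self, u, v, key) -> Optional[np.ndarray]:
        """Edge pixel path ordered from u to v (None if untraced)."""
        path = self.g.edges[u, v, key]["path"]
        if path is None:
            return None
        ru = np.asarray(self.g.nodes[u]["rc"])
        if np.linalg.norm(path[0] - ru) <= np.linalg.norm(path[-1] - ru):
            return path
        return path[::-1]

    def copy(self) -> "SkeletonGraph":
        return SkeletonGraph(self.g.copy(), self.pixel_size_um)


# ---------------------------------------------------------------------------
# operations


def preprocess(
    image: np.ndarray,
    window: int = 101,
    offset: float = 2000.0,
    invert: bool = False,
    min_object_px: int = 64,
) -> np.ndarray:
    """Adaptive local-mean threshold of one channel.

    A pixel is foreground when its intensity exceeds the mean over a
    ``window`` × ``window`` neighborhood by more than ``offset``; specks
    below ``min_object_px`` are removed. ``invert`` flips the contrast
    first (dark-signal images give the same mask as their bright-signal
    mirror).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {image.shape}")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    img = image.astype(float)
    if invert:
        img = img.max() - img
    local_mean = ndimage.uniform_filter(img, size=window, mode="reflect")
    mask = img > local_mean + offset
    if min_object_px > 0:
        mask = _remove_small(mask, min_object_px)
    return mask


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels = cc_label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return sizes[labels] >= min_px


def segment_body(
    mask: np.ndarray,
    pixel_size_um: float = 1.0,
    opening_radius: int = 4,
    closing_radius: int = 15,
) -> ExplantBody:
    """Delineate the explant body as the largest dense region of the mask.

    Opening with a disk larger than the neurite half-width removes thin
    processes first (local thresholding leaves the body as a dense rim
    plus partial interior, while neurites are thin). The surviving dense
    components — minor fragments below a quarter of the largest are
    discarded — are then consolidated by closing and hole filling, and
    the largest connected region is the body.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no explant found: mask is empty")
    core = opening(mask, disk(opening_radius))
    if not core.any():  # nothing dense; fall back to the raw mask
        core = mask
    labels = cc_label(core, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    core = sizes[labels] >= 0.25 * sizes.max()
    core &= labels > 0
    solid = ndimage.binary_fill_holes(closing(core, disk(closing_radius)))
    labels = cc_label(solid, connectivity=2)
    body = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1
    rows, cols = np.nonzero(body)
    return ExplantBody(
        mask=body,
        centroid=(float(rows.mean()), float(cols.mean())),
        projected_area_um2=float(body.sum()) * pixel_size_um**2,
        pixel_size_um=pixel_size_um,
    )


def _step_cost(a: np.ndarray, b: np.ndarray) -> float:
    return _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _path_length_um(path: np.ndarray, pixel_size_um: float) -> float:
    if len(path) < 2:
        return 0.0
    d = np.abs(np.diff(path, axis=0))
    steps = np.where((d[:, 0] > 0) & (d[:, 1] > 0), _SQRT2, 1.0)
    return float(steps.sum()) * pixel_size_um


def skeletonize_to_graph(
    mask: np.ndarray,
    body: ExplantBody,
    pixel_size_um: float,
    body_clearance_px: int = 2,
    min_fragment_px: int = 10,
) -> SkeletonGraph:
    """Skeletonize the outgrowth outside the body and convert it to a graph.

    Nodes sit at skeleton endpoints, junctions and body-boundary contacts
    (start nodes); edges carry the traced pixel path and its chain-code
    length. The body interior is excluded from the skeleton; an empty
    outgrowth yields a graph with zero edges.
    """
    mask = np.asarray(mask, dtype=bool)
    body_zone = dilation(body.mask, disk(body_clearance_px))
    outgrowth = mask & ~body_zone
    if min_fragment_px > 0:
        outgrowth = _remove_small(outgrowth, min_fragment_px)
    skel = skeletonize(outgrowth)
    contact_zone = dilation(body.mask, disk(body_clearance_px + 2))
    return _graph_from_skeleton(skel, contact_zone, pixel_size_um)


def _graph_from_skeleton(
    skel: np.ndarray, contact_zone: np.ndarray, pixel_size_um: float
) -> SkeletonGraph:
    h, w = skel.shape
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    ncount = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    body_adjacent = skel & contact_zone
    node_mask = skel & ((ncount != 2) | body_adjacent)

    g = nx.MultiGraph()
    node_labels, n_nodes = ndimage.label(node_mask, structure=np.ones((3, 3), dtype=int))
    label_at = {}
    for nid in range(1, n_nodes + 1):
        pix = np.argwhere(node_labels == nid)
        for r, c in pix:
            label_at[(r, c)] = nid
        g.add_node(
            nid,
            rc=tuple(pix.mean(axis=0)),
            pixels=[tuple(p) for p in pix],
            start=bool(body_adjacent[tuple(pix.T)].any()),
        )

    path_mask = skel & ~node_mask
    visited = np.zeros_like(skel, dtype=bool)

    def _skel_neighbors(r, c):
        for dr, dc in _N8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                yield rr, cc

    def _trace(origin_pix, first):
        """Walk path pixels from a node pixel until another node pixel."""
        path = [origin_pix, first]
        visited[first] = True
        prev, cur = origin_pix, first
        while True:
            nxt = None
            for nb in _skel_neighbors(*cur):
                if nb == prev:
                    continue
                if node_mask[nb]:
                    path.append(nb)
                    return path, label_at[nb]
                if path_mask[nb] and not visited[nb]:
                    nxt = nb
                    break
            if nxt is None:
                # dead-ends only occur on tiny loop artifacts
                return path, None
            visited[nxt] = True
            prev, cur = cur, nxt
            path.append(cur)

    seen_direct = set()
    for nid in range(1, n_nodes + 1):
        for pix in g.nodes[nid]["pixels"]:
            for nb in _skel_neighbors(*pix):
                if path_mask[nb] and not visited[nb]:
                    path, other = _trace(pix, nb)
                    if other is None:
                        continue
                    if other == nid and len(path) <= 4:
                        continue  # triangle artifact hugging a junction cluster
                    arr = np.array(path, dtype=float)
                    g.add_edge(nid, other, path=arr,
                               length_um=_path_length_um(arr, pixel_size_um))
                elif node_mask[nb] and label_at[nb] != nid:
                    key = (min(pix, nb), max(pix, nb))
                    if key in seen_direct:
                        continue
                    seen_direct.add(key)
                    arr = np.array([pix, nb], dtype=float)
                    g.add_edge(nid, label_at[nb], path=arr,
                               length_um=_path_length_um(arr, pixel_size_um))

    # isolated cycles (no endpoint/junction): promote one pixel to a node
    leftovers = path_mask & ~visited
    if leftovers.any():
        loop_labels, n_loops = ndimage.label(leftovers, structure=np.ones((3, 3), dtype=int))
        for lid in range(1, n_loops + 1):
            pix = tuple(np.argwhere(loop_labels == lid)[0])
            nid = g.number_of_nodes() + 1
            node_mask[pix] = True
            path_mask[pix] = False
            label_at[pix] = nid
            g.add_node(nid, rc=(float(pix[0]), float(pix[1])), pixels=[pix], start=False)
            for nb in _skel_neighbors(*pix):
                if path_mask[nb] and not visited[nb]:
                    path, other = _trace(pix, nb)
                    if other is not None:
                        arr = np.array(path, dtype=float)
                        g.add_edge(nid, other, path=arr,
                                   length_um=_path_length_um(arr, pixel_size_um))
    return SkeletonGraph(g, pixel_size_um)


def prune_graph(sg: SkeletonGraph, min_spur_um: float = 10.0) -> SkeletonGraph:
    """Remove terminal skeleton spurs shorter than ``min_spur_um``.

    A spur is a degree-1 non-start node whose single edge (shorter than
    the threshold) attaches to a branch node. After each sweep, degree-2
    non-start nodes are fused (their two edges concatenated) so the
    surviving path is re-joined; sweeps repeat to a fixpoint, making the
    operation idempotent.
    """
    if min_spur_um < 0:
        raise ValueError("min_spur_um must be >= 0")
    sg = sg.copy()
    g = sg.g
    changed = True
    while changed:
        changed = False
        if min_spur_um > 0:
            for n in list(g.nodes):
                if g.degree(n) != 1 or g.nodes[n].get("start", False):
                    continue
                u, v, key = next(iter(g.edges(n, keys=True)))
                other = v if u == n else u
                if g.edges[u, v, key]["length_um"] < min_spur_um and g.degree(other) >= 3:
                    g.remove_node(n)
                    changed = True
        for n in list(g.nodes):
            if g.degree(n) != 2 or g.nodes[n].get("start", False):
                continue
            incident = list(g.edges(n, keys=True))
            if len(incident) != 2:  # self-loop counts twice
                continue
            (u1, v1, k1), (u2, v2, k2) = incident
            a = v1 if u1 == n else u1
            b = v2 if u2 == n else u2
            if a == n or b == n:
                continue
            p1 = sg.oriented_path(n, a, k1)
            p2 = sg.oriented_path(n, b, k2)
            if p1 is None or p2 is None:
                merged = None
            else:
                merged = np.vstack([p1[::-1], p2[1:]])  # a ... n ... b
            length = g.edges[u1, v1, k1]["length_um"] + g.edges[u2, v2, k2]["length_um"]
            g.remove_node(n)
            g.add_edge(a, b, path=merged, length_um=length)
            changed = True
    sg._assign_roles()
    return sg


def _smoothed_length_um(path: np.ndarray, pixel_size_um: float, window: int = 7) -> float:
    """Euclidean length of the pixel path after endpoint-preserving
    moving-average smoothing — removes the staircase bias of the raw
    chain code."""
    if len(path) < 2:
        return 0.0
    if len(path) <= window:
        sm = path
    else:
        kernel = np.ones(window) / window
        sm = np.empty_like(path, dtype=float)
        for k in (0, 1):
            padded = np.concatenate(
                [np.full(window // 2, path[0, k]), path[:, k], np.full(window // 2, path[-1, k])]
            )
            sm[:, k] = np.convolve(padded, kernel, mode="valid")
        sm[0], sm[-1] = path[0], path[-1]
    return float(np.sum(np.linalg.norm(np.diff(sm, axis=0), axis=1))) * pixel_size_um


def extract_metrics(
    sg: SkeletonGraph,
    body: Optional[ExplantBody] = None,
) -> OutgrowthMetrics:
    """Morphometry from a (pruned) skeleton graph.

    Endings are degree-1 non-start nodes; start points are the
    body-contact nodes; the length of an ending is the geodesic distance
    along the graph to its nearest start point (chain-code weights route
    the shortest path; the reported length re-measures that path's pixel
    trace with staircase smoothing). Endings in components that contain
    no start node are measured from their component's node closest to the
    body and flagged ``disconnected``.
    """
    g = sg.g
    starts = [n for n in g.nodes if g.nodes[n].get("start", False)]
    endings = [n for n in g.nodes if g.degree(n) == 1 and not g.nodes[n].get("start", False)]
    branch_nodes = [n for n in g.nodes if g.degree(n) >= 3]
    total = sg.total_length_um()

    dist: dict = {}
    routes: dict = {}
    if starts:
        dist, routes = nx.multi_source_dijkstra(g, set(starts), weight="length_um")

    centroid = np.asarray(body.centroid) if body is not None else None
    # distance from any pixel to the body rim: compensates the clearance gap
    # between a start node and the true exit point on the body boundary
    dt_body = (
        ndimage.distance_transform_edt(~body.mask) if body is not None else None
    )
    pseudo_routes: dict = {}
    pseudo_starts: set = set()
    for e in endings:
        if e in dist or e in pseudo_routes:
            continue
        comp = nx.node_connected_component(g, e)
        if centroid is not None:
            pseudo = min(
                comp, key=lambda n: np.linalg.norm(np.asarray(g.nodes[n]["rc"]) - centroid)
            )
        else:
            pseudo = min(comp)
        pseudo_starts.add(pseudo)
        _, r_c = nx.single_source_dijkstra(g, pseudo, weight="length_um")
        pseudo_routes.update({n: r for n, r in r_c.items() if n in comp})

    rows = []
    for e in endings:
        if e in dist:
            route = routes[e]
            disconnected = False
        else:
            if e in pseudo_starts:
                continue  # the fragment's body-facing end is not a tip
            route = pseudo_routes[e]
            disconnected = True
        start_node = route[0]
        graph_len, refined = _route_lengths(sg, route)
        rc = g.nodes[e]["rc"]
        src = g.nodes[start_node]["rc"]
        if dt_body is not None and not disconnected:
            r0 = int(np.clip(round(src[0]), 0, dt_body.shape[0] - 1))
            c0 = int(np.clip(round(src[1]), 0, dt_body.shape[1] - 1))
            refined += float(dt_body[r0, c0]) * sg.pixel_size_um
        rows.append(
            {
                "ending_id": e,
                "r": rc[0],
                "c": rc[1],
                "start_id": start_node,
                "start_r": src[0],
                "start_c": src[1],
                "length_um": refined,
                "graph_length_um": graph_len,
                "disconnected": disconnected,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "ending_id", "r", "c", "start_id", "start_r", "start_c",
            "length_um", "graph_length_um", "disconnected",
        ],
    )
    lengths = table["length_um"].to_numpy(dtype=float) if len(table) else np.empty(0)
    return OutgrowthMetrics(
        n_endings=len(table),
        n_branch_points=len(branch_nodes),
        n_start_points=len(starts),
        lengths_um=lengths,
        median_length_um=float(np.median(lengths)) if lengths.size else None,
        longest_um=float(lengths.max()) if lengths.size else None,
        total_length_um=total,
        projected_area_um2=body.projected_area_um2 if body is not None else None,
        endings=table,
    )


def _route_lengths(sg: SkeletonGraph, route: list) -> tuple[float, float]:
    """(chain-code length, smoothed length) along a node route, picking the
    shortest parallel edge at every hop (ties by smallest key)."""
    g = sg.g
    if len(route) < 2:
        return 0.0, 0.0
    total = 0.0
    pieces = []
    for u, v in zip(route[:-1], route[1:]):
        key = min(g[u][v], key=lambda k: (g[u][v][k]["length_um"], k))
        total += g[u][v][key]["length_um"]
        pieces.append(sg.oriented_path(u, v, key))
    if any(p is None for p in pieces):
        return total, total  # untraced graph: declared lengths are exact
    full = pieces[0]
    for p in pieces[1:]:
        full = np.vstack([full, p[1:] if np.allclose(p[0], full[-1]) else p])
    return total, _smoothed_length_um(full, sg.pixel_size_um)


def analyze_image(
    channel: np.ndarray,
    pixel_size_um: float,
    window: int = 101,
    offset: float = 2000.0,
    min_spur_um: float = 10.0,
    invert: bool = False,
) -> tuple[np.ndarray, ExplantBody, SkeletonGraph, OutgrowthMetrics]:
    """Full chain on one neuronal-marker channel."""
    mask = preprocess(channel, window=window, offset=offset, invert=invert)
    body = segment_body(mask, pixel_size_um=pixel_size_um)
    sg = skeletonize_to_graph(mask, body, pixel_size_um)
    sg = prune_graph(sg, min_spur_um=min_spur_um)
    metrics = extract_metrics(sg, body)
    return mask, body, sg, metrics
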