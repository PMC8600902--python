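"""Collagen segmentation, fiber-network tracing, and morphological features.

The tracing follows the standard skeleton-graph recipe used by fiber
quantification toolkits: threshold the ROI, skeletonize the mask, prune
short spurs, declare skeleton points of degree >= 3 as crosslinks (adjacent
junction pixels merged into one), and read fibers off as maximal skeleton
paths between endpoints/crosslinks. Two paths meeting at a crosslink are
joined into one fiber when their incoming tangents continue smoothly
(default: direction change below 20 degrees).

The eight morphological features are: collagen area fraction; fiber count;
mean fiber length (um); mean fiber width (um, twice the mean distance
transform sampled along the skeleton); mean straightness (endpoint chord /
arc length); crosslink density (crosslinks per 100 um^2 of collagen mask);
mean skeleton spacing between consecutive crosslinks along a fiber (um);
and orientation concentration (resultant length of the doubled fiber
angles, 1 = perfectly aligned, 0 = uniform).

Empty networks yield zero-valued sentinel features rather than NaN so that
downstream standardization never propagates missing values; patients whose
collagen is too sparse to trace are expected to be excluded upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import skeletonize

from .image import SHGImage


class DegenerateImageError(ValueError):
    """Raised when a threshold is undefined (constant positive image)."""


@dataclass
class FiberNetwork:
    fibers: list[np.ndarray]          # polylines, (N, 2) pixel coords (x, y)
    crosslinks: list[tuple[float, float]]
    mask: np.ndarray
    pixel_size_um: float

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)


@dataclass
class MorphFeatures:
    collagen_area_fraction: float
    fiber_number: float
    mean_length_um: float
    mean_width_um: float
    mean_straightness: float
    crosslink_density: float          # crosslinks per 100 um^2 of collagen mask
    crosslink_space_um: float
    orientation_concentration: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.collagen_area_fraction,
                self.fiber_number,
                self.mean_length_um,
                self.mean_width_um,
                self.mean_straightness,
                self.crosslink_density,
                self.crosslink_space_um,
                self.orientation_concentration,
            ]
        )


def segment_collagen(
    image: SHGImage, method: str = "otsu", smoothing_sigma_um: float = 0.4
) -> np.ndarray:
    """Binary collagen mask via smoothed global thresholding.

    The default picks the global threshold maximizing between-class variance
    (Otsu) after light Gaussian smoothing. An all-zero image yields an empty
    mask; a constant positive image has no defined threshold and raises
    :class:`DegenerateImageError`.
    """
    pixels = image.pixels.astype(np.float64)
    lo, hi = float(pixels.min()), float(pixels.max())
    if lo == hi:
        if hi == 0.0:
            return np.zeros(image.shape, dtype=bool)
        raise DegenerateImageError("constant positive image: threshold undefined")
    if method != "otsu":
        raise ValueError(f"unknown segmentation method {method!r}")
    sigma_px = smoothing_sigma_um / image.pixel_size_um
    smoothed = gaussian(pixels, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else pixels
    return smoothed > threshold_otsu(smoothed)


# --------------------------------------------------------------------------
# skeleton graph tracing
# --------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph, excluding diagonal edges that close a
    triangle with an orthogonal pair (they create spurious junctions)."""
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    g.add_nodes_from(pixels)
    for (r, c) in pixels:
        for dr, dc in _NEIGHBORS:
            nb = (r + dr, c + dc)
            if nb not in pixels:
                continue
            if dr != 0 and dc != 0 and ((r + dr, c) in pixels or (r, c + dc) in pixels):
                continue  # reachable through an orthogonal neighbor
            g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def _prune_spurs(g: nx.Graph, min_len_px: float) -> None:
    """Iteratively remove endpoint branches shorter than min_len_px that end
    at a junction (true dangling spurs, not free-standing fibers)."""
    changed = True
    while changed:
        changed = False
        endpoints = [n for n in g.nodes if g.degree(n) == 1]
        for ep in endpoints:
            if ep not in g or g.degree(ep) != 1:
                continue
            path = [ep]
            length = 0.0
            cur, prev = ep, None
            hit_junction = False
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if g.degree(cur) >= 3 and cur != ep:
                    hit_junction = True
                    break
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["weight"]
                if length >= min_len_px:
                    break
                prev, cur = cur, nxt
                path.append(cur)
                if g.degree(cur) >= 3:
                    hit_junction = True
                    path.pop()  # keep the junction pixel
                    break
            if hit_junction and length < min_len_px:
                g.remove_nodes_from(path)
                changed = True


def _junction_clusters(g: nx.Graph) -> list[set]:
    junctions = {n for n in g.nodes if g.degree(n) >= 3}
    sub = g.subgraph(junctions)
    return [set(c) for c in nx.connected_components(sub)]


def _segments(g: nx.Graph, junction_pixels: set) -> list[list]:
    """Maximal degree-2 chains between node points (endpoints / junctions)."""
    node_points = junction_pixels | {n for n in g.nodes if g.degree(n) != 2}
    segments: list[list] = []
    visited_edges: set = set()

    def edge_key(a, b):
        return (a, b) if a <= b else (b, a)

    for start in node_points:
        for nb in g.neighbors(start):
            if edge_key(start, nb) in visited_edges:
                continue
            path = [start, nb]
            visited_edges.add(edge_key(start, nb))
            prev, cur = start, nb
            while cur not in node_points:
                nxt = [n for n in g.neighbors(cur) if n != prev]
                if not nxt:
                    break
                visited_edges.add(edge_key(cur, nxt[0]))
                prev, cur = cur, nxt[0]
                path.append(cur)
            segments.append(path)
    # isolated cycles (no node points) are traced as closed fibers
    seen = set()
    for seg in segments:
        seen.update(seg)
    for comp in nx.connected_components(g):
        if comp & seen or not (comp - junction_pixels):
            continue
        cycle = list(comp)
        if len(cycle) >= 3:
            start = cycle[0]
            path = [start]
            prev, cur = None, start
            while True:
                nxt = [n for n in g.neighbors(cur) if n != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                if cur == start:
                    path.append(cur)
                    break
                path.append(cur)
            segments.append(path)
            seen.update(path)
    return segments


def _smooth_polyline(pts: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing (endpoints pinned) to undo the staircase
    inflation of pixel-chain arc lengths."""
    if len(pts) < window:
        return pts.copy()
    sm = ndimage.uniform_filter1d(pts, size=window, axis=0, mode="nearest")
    sm[0], sm[-1] = pts[0], pts[-1]
    return sm


def _path_length(path: list) -> float:
    pts = np.asarray(path, float)
    if len(pts) < 2:
        return 0.0
    d = np.diff(pts, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def _tangent_into(path: list, at_start: bool, k: int = 5) -> np.ndarray:
    """Unit direction of the path as it leaves its start (or enters its end)."""
    pts = np.asarray(path, float)
    if at_start:
        seg = pts[: min(k, len(pts))]
        v = seg[-1] - seg[0]
    else:
        seg = pts[-min(k, len(pts)):]
        v = seg[-1] - seg[0]
    norm = np.hypot(v[0], v[1])
    return v / norm if norm > 0 else np.array([1.0, 0.0])


def extract_fiber_network(
    mask: np.ndarray,
    pixel_size_um: float,
    spur_min_um: float = 3.0,
    fiber_min_um: float = 5.0,
    continuation_angle_deg: float = 20.0,
) -> FiberNetwork:
    """Trace the fiber network from a binary collagen mask.

    An empty mask yields an empty network (not an error). Crosslinks are
    merged connected components of skeleton pixels with degree >= 3; their
    reported coordinates are component centroids in (x, y) pixel order.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return FiberNetwork([], [], mask, pixel_size_um)

    skel = skeletonize(mask)
    g = _skeleton_graph(skel)
    _prune_spurs(g, spur_min_um / pixel_size_um)

    clusters = _junction_clusters(g)
    junction_pixels = set().union(*clusters) if clusters else set()
    pixel_to_cluster: dict = {}
    for ci, cluster in enumerate(clusters):
        for p in cluster:
            pixel_to_cluster[p] = ci

    segments = _segments(g, junction_pixels)

    # smooth-continuation rule: at each junction cluster, pair up incident
    # segments whose tangents continue within the angle tolerance
    merged = _merge_continuations(segments, pixel_to_cluster, continuation_angle_deg)

    min_len_px = fiber_min_um / pixel_size_um
    fibers = []
    for path in merged:
        if _path_length(path) >= min_len_px and len(path) >= 2:
            pts = np.asarray(path, float)
            fibers.append(_smooth_polyline(pts[:, ::-1]))  # (row, col) -> (x, y)

    crosslinks = []
    for cluster in clusters:
        pts = np.asarray(list(cluster), float)
        crosslinks.append((float(pts[:, 1].mean()), float(pts[:, 0].mean())))
    return FiberNetwork(fibers, crosslinks, mask, pixel_size_um)


def _merge_continuations(
    segments: list[list], pixel_to_cluster: dict, tol_deg: float
) -> list[list]:
    """Join segment pairs that continue smoothly through a junction."""
    # collect (segment index, end) incidences per junction cluster
    incidence: dict[int, list[tuple[int, int]]] = {}
    for si, seg in enumerate(segments):
        for end, pixel in ((0, seg[0]), (1, seg[-1])):
            ci = pixel_to_cluster.get(pixel)
            if ci is not None:
                incidence.setdefault(ci, []).append((si, end))

    # union-find over segment endpoints to chain multiple merges
    parent = list(range(len(segments)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    joins: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for ci, ends in incidence.items():
        if len(ends) < 2:
            continue
        # outgoing direction of each incident segment, pointing away from junction
        dirs = []
        for si, end in ends:
            d = _tangent_into(segments[si], at_start=(end == 0))
            if end == 1:
                d = -d
            dirs.append(d)
        # greedy best-pair matching on straight-line continuation:
        # two segments continue if their outgoing directions are opposed
        import math

        flat = [(float(d[0]), float(d[1])) for d in dirs]
        candidates = []
        for a in range(len(ends)):
            ax, ay = flat[a]
            for b in range(a + 1, len(ends)):
                bx, by = flat[b]
                cosang = min(1.0, max(-1.0, -(ax * bx + ay * by)))
                turn = math.degrees(math.acos(cosang))
                if turn < tol_deg:
                    candidates.append((turn, a, b))
        used = set()
        for _, a, b in sorted(candidates):
            if a in used or b in used:
                continue
            if ends[a][0] == ends[b][0]:
                continue  # a segment does not continue into itself
            used.update((a, b))
            joins.append((ends[a], ends[b]))

    # assemble merged polylines by walking join links
    links: dict[tuple[int, int], tuple[int, int]] = {}
    for ea, eb in joins:
        links[ea] = eb
        links[eb] = ea

    consumed = [False] * len(segments)
    out: list[list] = []
    for si in range(len(segments)):
        if consumed[si]:
            continue
        # walk to the head of the chain
        chain = [(si, False)]  # (segment, reversed?)
        consumed[si] = True
        # extend forward from end 1
        cur, cur_end = si, 1
        while (cur, cur_end) in links:
            nsi, nend = links[(cur, cur_end)]
            if consumed[nsi]:
                break
            consumed[nsi] = True
            chain.append((nsi, nend == 1))
            cur, cur_end = nsi, 1 - nend
        # extend backward from end 0
        cur, cur_end = si, 0
        while (cur, cur_end) in links:
            nsi, nend = links[(cur, cur_end)]
            if consumed[nsi]:
                break
            consumed[nsi] = True
            chain.insert(0, (nsi, nend == 0))
            cur, cur_end = nsi, 1 - nend
        path: list = []
        for seg_i, rev in chain:
            pts = segments[seg_i][::-1] if rev else segments[seg_i]
            if path and path[-1] == pts[0]:
                path.extend(pts[1:])
            else:
                path.extend(pts)
        out.append(path)
    return out


# --------------------------------------------------------------------------
# morphological features
# --------------------------------------------------------------------------

def fiber_angles_deg(network: FiberNetwork) -> np.ndarray:
    """Axial chord orientation of each traced fiber, degrees in [0, 180)."""
    angles = []
    for f in network.fibers:
        v = f[-1] - f[0]
        if np.hypot(v[0], v[1]) == 0:
            continue
        angles.append(np.degrees(np.arctan2(v[1], v[0])) % 180.0)
    return np.asarray(angles)


def orientation_concentration(angles_deg: np.ndarray) -> float:
    """Resultant length of doubled angles: 1 = aligned, 0 = uniform."""
    if len(angles_deg) == 0:
        return 0.0
    doubled = np.radians(2.0 * np.asarray(angles_deg, float))
    return float(np.hypot(np.mean(np.cos(doubled)), np.mean(np.sin(doubled))))


def compute_morph_features(network: FiberNetwork) -> MorphFeatures:
    """The eight morphological features of a traced network.

    Empty networks return the zero-sentinel convention documented in the
    module docstring.
    """
    px = network.pixel_size_um
    mask = network.mask
    area_fraction = float(mask.mean()) if mask.size else 0.0
    if not network.fibers:
        return MorphFeatures(area_fraction, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    lengths = np.array([_polyline_length(f) for f in network.fibers]) * px
    straightness = np.array([_polyline_straightness(f) for f in network.fibers])

    # width: 2 x mean distance transform sampled along all fiber skeleton
    # pixels, minus one pixel for the half-pixel bias at both boundaries
    dist = ndimage.distance_transform_edt(mask)
    samples = []
    for f in network.fibers:
        cols = np.clip(np.round(f[:, 0]).astype(int), 0, mask.shape[1] - 1)
        rows = np.clip(np.round(f[:, 1]).astype(int), 0, mask.shape[0] - 1)
        samples.append(dist[rows, cols])
    width_um = max(2.0 * float(np.mean(np.concatenate(samples))) - 1.0, 1.0) * px

    mask_area_um2 = float(mask.sum()) * px * px
    n_cross = len(network.crosslinks)
    crosslink_density = n_cross / (mask_area_um2 / 100.0) if mask_area_um2 > 0 else 0.0
    crosslink_space = _crosslink_spacing_um(network)

    angles = fiber_angles_deg(network)
    return MorphFeatures(
        collagen_area_fraction=area_fraction,
        fiber_number=float(len(network.fibers)),
        mean_length_um=float(lengths.mean()),
        mean_width_um=width_um,
        mean_straightness=float(straightness.mean()),
        crosslink_density=crosslink_density,
        crosslink_space_um=crosslink_space,
        orientation_concentration=orientation_concentration(angles),
    )


def _polyline_length(f: np.ndarray) -> float:
    d = np.diff(f, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def _polyline_straightness(f: np.ndarray) -> float:
    arc = _polyline_length(f)
    if arc == 0:
        return 1.0
    v = f[-1] - f[0]
    return float(np.hypot(v[0], v[1]) / arc)


def _crosslink_spacing_um(network: FiberNetwork, snap_px: float = 2.0) -> float:
    """Mean along-fiber arc distance between consecutive crosslinks.

    Crosslinks are snapped to the nearest fiber vertex within `snap_px`;
    fibers carrying fewer than two crosslinks are excluded. Returns the
    zero sentinel when no fiber carries two crosslinks.
    """
    if len(network.crosslinks) < 2:
        return 0.0
    from scipy.spatial import cKDTree

    cross = np.asarray(network.crosslinks, float)
    spacings = []
    for f in network.fibers:
        d = np.diff(f, axis=0)
        arclen = np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])
        dists, idx = cKDTree(f).query(cross, distance_upper_bound=snap_px)
        positions = sorted({arclen[j] for dist, j in zip(dists, idx) if np.isfinite(dist)})
        if len(positions) >= 2:
            spacings.extend(np.diff(positions))
    if not spacings:
        return 0.0
    return float(np.mean(spacings)) * network.pixel_size_um
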