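"""Computational domain: grid, tumor/normal tissue map, capillary network.

The domain is a 2D structured grid of square-ish cells holding a roughly
central circular tumor embedded in normal tissue.  The capillary network is
a node/segment graph embedded in the domain, either generated synthetically
(two parent vessels on opposite edges — two inlets, one outlet — with
seeded random-walk sprouts growing into the tumor) or imported from a
binary vessel-mask raster via skeletonization.

Cells are indexed row-major ``field[j, i]`` with ``i`` along x and ``j``
along y, 0-based, positions at cell centers, all lengths in meters.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .params import convert_pressure

INLET = "inlet"
OUTLET = "outlet"
INTERIOR = "interior"


@dataclass
class SimulationGrid:
    nx: int
    ny: int
    dx: float
    dy: float
    origin: tuple[float, float] = (0.0, 0.0)
    #: fixed physical thickness of the pseudo-3D tissue slab (m); per-volume
    #: densities like S/V use it, so refining the grid leaves them invariant
    thickness: float = 2e-5

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("need nx, ny >= 3")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be > 0")
        if self.thickness <= 0:
            raise ValueError("slab thickness must be > 0")

    @property
    def width(self) -> float:
        return self.nx * self.dx

    @property
    def height(self) -> float:
        return self.ny * self.dy

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def slab_thickness(self) -> float:
        """Pseudo-3D thickness used to express per-volume densities."""
        return self.thickness

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.dy

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        return (self.origin[0] + (i + 0.5) * self.dx,
                self.origin[1] + (j + 0.5) * self.dy)


def build_grid(width: float, height: float, nx: int, ny: int,
               origin: tuple[float, float] = (0.0, 0.0),
               thickness: float = 2e-5) -> SimulationGrid:
    """Structured grid of ``nx``×``ny`` cells covering width×height meters."""
    if width <= 0 or height <= 0:
        raise ValueError("domain dimensions must be > 0")
    if nx < 3 or ny < 3:
        raise ValueError("need nx, ny >= 3")
    return SimulationGrid(nx=nx, ny=ny, dx=width / nx, dy=height / ny,
                          origin=origin, thickness=thickness)


@dataclass
class TissueMap:
    """Per-cell tumor/normal labels; True marks tumor cells."""

    tumor_mask: np.ndarray              # bool, shape (ny, nx)
    tumor_center: tuple[float, float] | None = None
    tumor_radius: float | None = None

    @property
    def n_tumor_cells(self) -> int:
        return int(self.tumor_mask.sum())


def make_circular_tumor(grid: SimulationGrid, center: tuple[float, float],
                        radius: float) -> TissueMap:
    """Label cells whose centers fall inside the circle as tumor.

    The circle must lie strictly inside the domain so that a rim of normal
    tissue separates the tumor from the outer boundary.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    x0, y0 = grid.origin
    cx, cy = center
    if radius > 0 and not (
        x0 < cx - radius and cx + radius < x0 + grid.width
        and y0 < cy - radius and cy + radius < y0 + grid.height
    ):
        raise ValueError("tumor circle must lie strictly inside the domain")
    X, Y = np.meshgrid(grid.x_centers(), grid.y_centers())
    mask = (X - cx) ** 2 + (Y - cy) ** 2 < radius**2
    return TissueMap(tumor_mask=mask, tumor_center=(cx, cy),
                     tumor_radius=radius)


def rescale_tumor(grid: SimulationGrid, tissue: TissueMap,
                  survival_fraction: float) -> TissueMap:
    """Shrink a circular tumor after partial kill: area ∝ cell number.

    The new radius is ``R·sqrt(survival_fraction)``; the vascular network is
    deliberately left untouched (the microvascular density distribution is
    held fixed across treatment cycles).
    """
    if not 0.0 < survival_fraction <= 1.0:
        raise ValueError("survival_fraction must be in (0,1]")
    if tissue.tumor_center is None or tissue.tumor_radius is None:
        raise ValueError("rescale requires a circular tumor")
    new_radius = tissue.tumor_radius * math.sqrt(survival_fraction)
    return make_circular_tumor(grid, tissue.tumor_center, new_radius)


# --------------------------------------------------------------------------
# Vascular network
# --------------------------------------------------------------------------

@dataclass
class VascularNetwork:
    """Node/segment capillary graph with boundary blood pressures."""

    positions: np.ndarray                    # (n_nodes, 2) m
    segments: list[tuple[int, int, float]]   # (node_a, node_b, radius m)
    boundary_pressures: dict[int, float] = field(default_factory=dict)  # Pa
    node_kind: dict[int, str] = field(default_factory=dict)  # inlet/outlet

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def segment_length(self, k: int) -> float:
        a, b, _ = self.segments[k]
        return float(np.linalg.norm(self.positions[a] - self.positions[b]))

    def segment_lengths(self) -> np.ndarray:
        return np.array([self.segment_length(k)
                         for k in range(len(self.segments))])

    def total_length(self) -> float:
        return float(self.segment_lengths().sum())

    def total_surface(self) -> float:
        """Total lateral (cylindrical) vessel surface, m² (2πr·l summed)."""
        return float(sum(2.0 * np.pi * r * self.segment_length(k)
                         for k, (_, _, r) in enumerate(self.segments)))

    def kind(self, node: int) -> str:
        return self.node_kind.get(node, INTERIOR)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from((a, b) for a, b, _ in self.segments)
        return g

    def validate(self, grid: SimulationGrid | None = None) -> None:
        if not self.segments:
            raise ValueError("network has no segments")
        lengths = self.segment_lengths()
        if np.any(lengths <= 0):
            raise ValueError("zero-length segment")
        kinds = set(self.node_kind.values())
        if INLET not in kinds or OUTLET not in kinds:
            raise ValueError("need at least one inlet and one outlet")
        # every connected component must be anchored by a boundary pressure
        for comp in nx.connected_components(self.graph()):
            if not any(n in self.boundary_pressures for n in comp):
                raise ValueError("component without boundary pressure node")
        if grid is not None:
            x0, y0 = grid.origin
            x1, y1 = x0 + grid.width, y0 + grid.height
            pos = self.positions
            eps = 1e-12
            if (pos[:, 0].min() < x0 - eps or pos[:, 0].max() > x1 + eps
                    or pos[:, 1].min() < y0 - eps or pos[:, 1].max() > y1 + eps):
                raise ValueError("network extends outside the domain")

    # -- serialization ------------------------------------------------------

    def to_csv(self) -> str:
        """Edge list CSV: node ids, end coordinates, radius, kinds, pressures."""
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["node_a", "node_b", "x_a", "y_a", "x_b", "y_b", "radius",
                    "kind_a", "kind_b", "pressure_a", "pressure_b"])
        for a, b, r in self.segments:
            w.writerow([
                a, b,
                repr(float(self.positions[a][0])), repr(float(self.positions[a][1])),
                repr(float(self.positions[b][0])), repr(float(self.positions[b][1])),
                repr(float(r)),
                self.kind(a), self.kind(b),
                repr(float(self.boundary_pressures.get(a, math.nan))),
                repr(float(self.boundary_pressures.get(b, math.nan))),
            ])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "VascularNetwork":
        rows = list(csv.DictReader(io.StringIO(text)))
        if not rows:
            raise ValueError("empty network CSV")
        pos: dict[int, tuple[float, float]] = {}
        segments = []
        pressures: dict[int, float] = {}
        kinds: dict[int, str] = {}
        for row in rows:
            a, b = int(row["node_a"]), int(row["node_b"])
            pos[a] = (float(row["x_a"]), float(row["y_a"]))
            pos[b] = (float(row["x_b"]), float(row["y_b"]))
            segments.append((a, b, float(row["radius"])))
            for node, kk, pk in ((a, "kind_a", "pressure_a"),
                                 (b, "kind_b", "pressure_b")):
                if row[kk] != INTERIOR:
                    kinds[node] = row[kk]
                p = float(row[pk])
                if not math.isnan(p):
                    pressures[node] = p
        n = max(pos) + 1
        positions = np.zeros((n, 2))
        for k, xy in pos.items():
            positions[k] = xy
        return cls(positions=positions, segments=segments,
                   boundary_pressures=pressures, node_kind=kinds)

    def to_graphml(self, path: str) -> None:
        g = nx.Graph()
        for n in range(self.n_nodes):
            g.add_node(n, x=float(self.positions[n, 0]),
                       y=float(self.positions[n, 1]), kind=self.kind(n),
                       pressure=float(self.boundary_pressures.get(n, math.nan)))
        for a, b, r in self.segments:
            g.add_edge(a, b, radius=float(r))
        nx.write_graphml(g, path)


# --------------------------------------------------------------------------
# Synthetic generator
# --------------------------------------------------------------------------

def generate_synthetic_vasculature(
    grid: SimulationGrid,
    tissue: TissueMap,
    seed: int = 0,
    n_trunk_points: int = 7,
    n_sprouts: int = 14,
    step: float | None = None,
    drift: float = 0.65,
    parent_radius: float = 7.5e-6,
    sprout_radius: float = 5e-6,
    inlet_pressure: float = convert_pressure(25.0),
    outlet_pressure: float = convert_pressure(10.0),
    bridge_distance: float | None = None,
    max_steps: int = 400,
) -> VascularNetwork:
    """Seeded synthetic capillary network feeding a central tumor.

    Two parent vessels run along the left and right domain edges.  The left
    parent carries the two inlet nodes (its two ends); the right parent
    carries the single outlet (its lower end).  ``n_sprouts`` capillary
    sprouts grow from trunk points by a random walk with a drift toward
    (and through) the tumor; sprout tips near the opposite parent's tree are
    anastomosed so the default network forms one connected, perfusable
    component with elevated vascular surface density inside the tumor.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    x0, y0 = grid.origin
    W, H = grid.width, grid.height
    if step is None:
        step = W / 50.0
    if bridge_distance is None:
        bridge_distance = 0.25 * W
    margin = 0.04 * min(W, H)
    if tissue.tumor_center is None:
        center = (x0 + W / 2, y0 + H / 2)
        t_radius = 0.25 * min(W, H)
    else:
        center = tissue.tumor_center
        t_radius = tissue.tumor_radius or 0.25 * min(W, H)

    positions: list[tuple[float, float]] = []
    segments: list[tuple[int, int, float]] = []

    def add_node(x: float, y: float) -> int:
        positions.append((float(np.clip(x, x0 + margin * 0.25, x0 + W - margin * 0.25)),
                          float(np.clip(y, y0 + margin * 0.25, y0 + H - margin * 0.25))))
        return len(positions) - 1

    ys = np.linspace(y0 + margin, y0 + H - margin, n_trunk_points)
    left_trunk = [add_node(x0 + margin, y) for y in ys]
    right_trunk = [add_node(x0 + W - margin, y) for y in ys]
    for chain in (left_trunk, right_trunk):
        for a, b in zip(chain[:-1], chain[1:]):
            segments.append((a, b, parent_radius))

    boundary = {
        left_trunk[0]: inlet_pressure,
        left_trunk[-1]: inlet_pressure,
        right_trunk[0]: outlet_pressure,
    }
    kinds = {left_trunk[0]: INLET, left_trunk[-1]: INLET,
             right_trunk[0]: OUTLET}

    left_nodes = set(left_trunk)
    right_nodes = set(right_trunk)
    tips: list[tuple[int, bool]] = []    # (tip node, from_left)

    for s in range(n_sprouts):
        from_left = s % 2 == 0
        trunk = left_trunk if from_left else right_trunk
        side_nodes = left_nodes if from_left else right_nodes
        start = trunk[1 + (s // 2) % max(1, n_trunk_points - 2)]
        # target: a point inside the tumor (uniform over a disc, biased inward)
        u, ang = rng.uniform(), rng.uniform(0, 2 * np.pi)
        target = np.array([center[0] + 0.75 * t_radius * math.sqrt(u) * math.cos(ang),
                           center[1] + 0.75 * t_radius * math.sqrt(u) * math.sin(ang)])
        pos = np.array(positions[start])
        prev_dir = (target - pos)
        prev_dir /= np.linalg.norm(prev_dir) + 1e-300
        node = start
        for _ in range(max_steps):
            to_target = target - pos
            dist = np.linalg.norm(to_target)
            if dist < step:
                break
            d = (drift * to_target / dist
                 + (1.0 - drift) * rng.normal(size=2)
                 + 0.3 * prev_dir)
            d /= np.linalg.norm(d) + 1e-300
            pos = pos + step * d
            prev_dir = d
            nxt = add_node(pos[0], pos[1])
            pos = np.array(positions[nxt])
            segments.append((node, nxt, sprout_radius))
            side_nodes.add(nxt)
            node = nxt
        tips.append((node, from_left))

    # anastomose sprout tips with the opposite tree so flow can cross
    pos_arr = np.array(positions) if positions else np.zeros((0, 2))
    bridged = False
    for tip, from_left in tips:
        other = right_nodes if from_left else left_nodes
        other_idx = np.array(sorted(other - {tip}))
        if other_idx.size == 0:
            continue
        d = np.linalg.norm(pos_arr[other_idx] - pos_arr[tip], axis=1)
        k = int(np.argmin(d))
        if d[k] < bridge_distance and d[k] > 0:
            segments.append((tip, int(other_idx[k]), sprout_radius))
            bridged = True
    if tips and not bridged:
        # guarantee at least one left-right connection
        li = np.array(sorted(left_nodes))
        ri = np.array(sorted(right_nodes))
        d = np.linalg.norm(pos_arr[li][:, None, :] - pos_arr[ri][None, :, :],
                           axis=2)
        a, b = np.unravel_index(np.argmin(d), d.shape)
        segments.append((int(li[a]), int(ri[b]), sprout_radius))

    net = VascularNetwork(positions=np.array(positions), segments=segments,
                          boundary_pressures=boundary, node_kind=kinds)
    net.validate(grid)
    return net


# --------------------------------------------------------------------------
# Rasterization
# --------------------------------------------------------------------------

def traverse_cells(grid: SimulationGrid, p0, p1):
    """Cells crossed by segment p0→p1 with the in-cell lengths.

    Returns ``(i_idx, j_idx, lengths)`` arrays; lengths sum to |p1−p0|.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L = float(np.linalg.norm(d))
    if L == 0.0:
        return (np.zeros(0, dtype=int), np.zeros(0, dtype=int), np.zeros(0))
    ts = [0.0, 1.0]
    x0, y0 = grid.origin
    if d[0] != 0.0:
        i_lines = np.arange(1, grid.nx)
        t = (x0 + i_lines * grid.dx - p0[0]) / d[0]
        ts.extend(t[(t > 0) & (t < 1)])
    if d[1] != 0.0:
        j_lines = np.arange(1, grid.ny)
        t = (y0 + j_lines * grid.dy - p0[1]) / d[1]
        ts.extend(t[(t > 0) & (t < 1)])
    ts = np.unique(np.asarray(ts))
    mids = p0[None, :] + 0.5 * (ts[:-1] + ts[1:])[:, None] * d[None, :]
    seg_len = np.diff(ts) * L
    ii = np.clip(((mids[:, 0] - x0) / grid.dx).astype(int), 0, grid.nx - 1)
    jj = np.clip(((mids[:, 1] - y0) / grid.dy).astype(int), 0, grid.ny - 1)
    keep = seg_len > 0
    return ii[keep], jj[keep], seg_len[keep]


def rasterize_network(network: VascularNetwork,
                      grid: SimulationGrid) -> np.ndarray:
    """Per-cell vascular surface density S/V (m⁻¹).

    Each segment's lateral surface 2πr·l is spread over the cells it
    traverses in proportion to in-cell length; the per-cell volume uses the
    grid's pseudo-3D slab thickness.  Conserves total surface exactly.
    """
    sv = np.zeros((grid.ny, grid.nx))
    cell_volume = grid.cell_area * grid.slab_thickness
    for a, b, r in network.segments:
        ii, jj, ll = traverse_cells(grid, network.positions[a],
                                    network.positions[b])
        np.add.at(sv, (jj, ii), 2.0 * np.pi * r * ll / cell_volume)
    return sv


# --------------------------------------------------------------------------
# Mask import
# --------------------------------------------------------------------------

def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rr, cc = np.nonzero(skel)
    pix = set(zip(rr.tolist(), cc.tolist()))
    for r, c in pix:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                if (r + dr, c + dc) in pix:
                    g.add_edge((r, c), (r + dr, c + dc))
    return g


def _simplify_polyline(points: np.ndarray, tol: float) -> np.ndarray:
    """Douglas–Peucker simplification (tolerance in same units as points)."""
    if len(points) <= 2:
        return points
    start, end = points[0], points[-1]
    chord = end - start
    nrm = np.linalg.norm(chord)
    if nrm == 0:
        dist = np.linalg.norm(points - start, axis=1)
    else:
        rel = points - start
        dist = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / nrm
    k = int(np.argmax(dist))
    if dist[k] <= tol:
        return np.array([start, end])
    left = _simplify_polyline(points[: k + 1], tol)
    right = _simplify_polyline(points[k:], tol)
    return np.vstack([left[:-1], right])


def import_vessel_mask(
    mask: np.ndarray,
    pixel_size: float,
    boundary_spec: list[dict],
    radius: float = 5e-6,
    simplify_tol_px: float = 0.8,
    origin: tuple[float, float] = (0.0, 0.0),
) -> VascularNetwork:
    """Reconstruct a vessel network from a binary raster mask.

    The foreground is skeletonized, skeleton branches (between endpoints and
    junctions) are vectorized into polylines, simplified, and converted to
    segments of uniform ``radius``.  ``boundary_spec`` is a list of
    ``{"pixel": (row, col), "pressure": Pa, "kind": "inlet"|"outlet"}``
    entries attached to the nearest reconstructed node.
    """
    from skimage.morphology import skeletonize

    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("vessel mask has empty foreground")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    skel = skeletonize(mask)
    g = _skeleton_graph(skel)

    # endpoints (deg 1) and junctions (deg ≥ 3); 8-connected junctions form
    # small clusters which are collapsed to single graph nodes (centroids)
    special = {n for n in g if g.degree(n) != 2}
    if not special:       # pure cycle(s): break each at an arbitrary pixel
        special = {sorted(comp)[0] for comp in nx.connected_components(g)}
    cluster_of: dict[tuple[int, int], int] = {}
    cluster_pixels: list[list[tuple[int, int]]] = []
    for comp in nx.connected_components(g.subgraph(special)):
        cid = len(cluster_pixels)
        cluster_pixels.append(sorted(comp))
        for p in comp:
            cluster_of[p] = cid

    polylines: list[tuple[int, int, list[tuple[int, int]]]] = []
    visited: set[tuple[int, int]] = set()      # interior (deg-2) pixels

    for start in sorted(special):
        for first in sorted(g.neighbors(start)):
            if first in special or first in visited:
                continue
            path = [start, first]
            visited.add(first)
            prev, cur = start, first
            while cur not in special:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
                if cur not in special:
                    visited.add(cur)
            end_cluster = cluster_of.get(path[-1], cluster_of[start])
            polylines.append((cluster_of[start], end_cluster, path))

    def to_xy(rc):
        r, c = rc
        return (origin[0] + (c + 0.5) * pixel_size,
                origin[1] + (r + 0.5) * pixel_size)

    positions: list[tuple[float, float]] = []
    segments: list[tuple[int, int, float]] = []
    cluster_node: dict[int, int] = {}

    def cluster_nid(cid: int) -> int:
        if cid not in cluster_node:
            pix = np.array(cluster_pixels[cid], dtype=float)
            cluster_node[cid] = len(positions)
            positions.append(to_xy(pix.mean(axis=0)))
        return cluster_node[cid]

    for cid_a, cid_b, path in polylines:
        pts = np.array(path, dtype=float)
        simple = _simplify_polyline(pts, simplify_tol_px)
        chain = [cluster_nid(cid_a)]
        for p in simple[1:-1]:
            chain.append(len(positions))
            positions.append(to_xy(p))
        chain.append(cluster_nid(cid_b))
        for a, b in zip(chain[:-1], chain[1:]):
            if a != b and positions[a] != positions[b]:
                segments.append((a, b, radius))

    if not segments:
        raise ValueError("mask skeleton produced no branches")

    positions_arr = np.array(positions)
    pressures: dict[int, float] = {}
    kinds: dict[int, str] = {}
    for spec in boundary_spec:
        px = np.array(to_xy(tuple(spec["pixel"])))
        d = np.linalg.norm(positions_arr - px, axis=1)
        node = int(np.argmin(d))
        if d[node] > 3.0 * pixel_size:
            raise ValueError(f"boundary pixel {spec['pixel']} is not on the "
                             "reconstructed skeleton")
        pressures[node] = float(spec["pressure"])
        kinds[node] = spec.get("kind", INLET)

    return VascularNetwork(positions=positions_arr, segments=segments,
                           boundary_pressures=pressures, node_kind=kinds)


def rasterize_to_mask(network: VascularNetwork, shape: tuple[int, int],
                      pixel_size: float,
                      origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Draw the network's centerlines onto a binary pixel raster."""
    from skimage.draw import line

    out = np.zeros(shape, dtype=bool)
    for a, b, _ in network.segments:
        (xa, ya), (xb, yb) = network.positions[a], network.positions[b]
        ra = int(np.clip((ya - origin[1]) / pixel_size, 0, shape[0] - 1))
        ca = int(np.clip((xa - origin[0]) / pixel_size, 0, shape[1] - 1))
        rb = int(np.clip((yb - origin[1]) / pixel_size, 0, shape[0] - 1))
        cb = int(np.clip((xb - origin[0]) / pixel_size, 0, shape[1] - 1))
        rr, cc = line(ra, ca, rb, cb)
        out[rr, cc] = True
    return out
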