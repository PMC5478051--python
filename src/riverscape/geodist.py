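"""The three geographic distance engines.

* great-circle (haversine) distance, accounting for Earth curvature;
* altitude least-cost-path distance over a raster with a pluggable
  conductance function and geo-correction (conductances divided by the
  true inter-cell-center distance so path costs carry length units);
* river-network distance along dendritic networks, with sample points
  snapped to the nearest river and pairs in disconnected basins
  treated as missing data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString, Point

from .core import (
    EARTH_RADIUS_M,
    DistanceMatrix,
    Raster,
    RiverNetwork,
    SampleSet,
    _node_key,
    haversine_m,
    haversine_matrix,
)
from .errors import ArgumentError

__all__ = [
    "TransitionSpec",
    "haversine_m",
    "haversine_matrix",
    "snap_to_network",
    "build_river_graph",
    "river_distance_matrix",
    "lcp_distance_matrix",
]


def _inverse_mean_altitude(h1, h2):
    return 2.0 / (h1 + h2)


#: Named conductance functions usable in :class:`TransitionSpec`.
CONDUCTANCE_FUNCTIONS: dict[str, Callable] = {
    "inverse_mean_altitude": _inverse_mean_altitude,
}


@dataclass
class TransitionSpec:
    """How raster cells connect for the least-cost path.

    The neighborhood is 8-connected. ``conductance_fn`` names a
    function of the two (floored) cell altitudes returning a strictly
    positive conductance; the default makes higher terrain more
    resistant. ``altitude_floor`` guards against division by tiny or
    non-positive elevations.
    """

    conductance_fn: str = "inverse_mean_altitude"
    altitude_floor: float = 1.0
    neighborhood: int = 8

    def conductance(self) -> Callable:
        if self.neighborhood != 8:
            raise ArgumentError("only the 8-connected neighborhood is supported")
        try:
            return CONDUCTANCE_FUNCTIONS[self.conductance_fn]
        except KeyError:
            raise ArgumentError(
                f"unknown conductance function {self.conductance_fn!r}; "
                f"available: {sorted(CONDUCTANCE_FUNCTIONS)}"
            ) from None


# ---------------------------------------------------------------------------
# snapping
# ---------------------------------------------------------------------------

def _local_frame(lon0: float, lat0: float):
    """Meters-per-degree scale factors of the equirectangular frame
    centered at (lon0, lat0)."""
    kx = EARTH_RADIUS_M * math.radians(1.0) * math.cos(math.radians(lat0))
    ky = EARTH_RADIUS_M * math.radians(1.0)
    return kx, ky


def snap_to_network(samples: SampleSet, net: RiverNetwork) -> SampleSet:
    """Move each sample to the nearest point on the river network.

    Nearness is evaluated in a local equirectangular frame centered on
    the sample, so the projection onto each arc is planar but the frame
    distortion stays negligible. The returned sample set records the
    offset moved (meters), the arc hit and the position along it, and
    inherits the arc's basin label.
    """
    if net.n_arcs == 0:
        raise ArgumentError("cannot snap to an empty network")
    arc_lengths = net.arc_lengths_m()
    n = samples.n
    new_lon = np.empty(n)
    new_lat = np.empty(n)
    offset = np.empty(n)
    arc_index = np.empty(n, dtype=int)
    arc_pos = np.empty(n)
    basin = []
    for k in range(n):
        lon0, lat0 = samples.lon[k], samples.lat[k]
        kx, ky = _local_frame(lon0, lat0)
        pt = Point(0.0, 0.0)
        best = (math.inf, -1, 0.0, (lon0, lat0))
        for a, arc in enumerate(net.arcs):
            line = LineString(
                np.column_stack(((arc[:, 0] - lon0) * kx, (arc[:, 1] - lat0) * ky))
            )
            proj = line.project(pt)
            cand = line.interpolate(proj)
            dist = pt.distance(cand)
            if dist < best[0]:
                frac = proj / line.length if line.length > 0 else 0.0
                snapped = (lon0 + cand.x / kx, lat0 + cand.y / ky)
                best = (dist, a, frac * arc_lengths[a], snapped)
        dist, a, pos_m, (slon, slat) = best
        new_lon[k], new_lat[k] = slon, slat
        offset[k] = haversine_m(lon0, lat0, slon, slat)
        arc_index[k] = a
        arc_pos[k] = pos_m
        basin.append(net.basin_ids[a])
    return SampleSet(
        ids=list(samples.ids),
        lon=new_lon,
        lat=new_lat,
        basin=basin,
        clade=list(samples.clade),
        snap_offset=offset,
        arc_index=arc_index,
        arc_pos_m=arc_pos,
    )


# ---------------------------------------------------------------------------
# river-network distance
# ---------------------------------------------------------------------------

def build_river_graph(samples: SampleSet, net: RiverNetwork) -> nx.Graph:
    """Network graph with snapped samples inserted as nodes.

    Nodes are quantized arc endpoints (junctions matched within 1e-6
    degrees) plus one ``("sample", id)`` node per snapped sample,
    inserted by splitting its arc at the snap position; edge weights
    are haversine polyline lengths in meters.
    """
    if not samples.is_snapped:
        raise ArgumentError("river graph construction requires snapped samples")
    g = nx.Graph()
    arc_lengths = net.arc_lengths_m()
    # samples grouped by arc, ordered by position along the arc
    by_arc: dict[int, list[int]] = {}
    for k in range(samples.n):
        by_arc.setdefault(int(samples.arc_index[k]), []).append(k)
    for a, arc in enumerate(net.arcs):
        u = _node_key(*arc[0])
        v = _node_key(*arc[-1])
        stops: list[tuple[float, object]] = [(0.0, u), (arc_lengths[a], v)]
        for k in by_arc.get(a, []):
            pos = float(np.clip(samples.arc_pos_m[k], 0.0, arc_lengths[a]))
            stops.append((pos, ("sample", samples.ids[k])))
        stops.sort(key=lambda t: t[0])
        for (p0, n0), (p1, n1) in zip(stops[:-1], stops[1:]):
            if n0 == n1:
                continue
            w = p1 - p0
            # parallel arcs / repeat visits: keep the shorter connection
            if g.has_edge(n0, n1):
                w = min(w, g[n0][n1]["weight"])
            g.add_edge(n0, n1, weight=w)
    return g


def river_distance_matrix(samples: SampleSet, net: RiverNetwork) -> DistanceMatrix:
    """Shortest-path distances along the river network (meters).

    Requires snapped samples (see :func:`snap_to_network`). Pairs of
    samples lying in different connected components (isolated basins)
    get a missing (NaN) entry.
    """
    g = build_river_graph(samples, net)
    n = samples.n
    vals = np.full((n, n), np.nan)
    np.fill_diagonal(vals, 0.0)
    node_of = {k: ("sample", samples.ids[k]) for k in range(n)}
    for k in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, node_of[k], weight="weight")
        for j in range(n):
            d = lengths.get(node_of[j])
            if d is not None:
                vals[k, j] = d
    vals = np.where(
        np.isfinite(vals) & np.isfinite(vals.T), (vals + vals.T) / 2.0, np.nan
    )
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(samples.ids), vals)


# ---------------------------------------------------------------------------
# least-cost path over an altitude raster
# ---------------------------------------------------------------------------

def _lcp_graph(raster: Raster, spec: TransitionSpec):
    """Sparse 8-connected cost graph over raster cells.

    Edge cost = inter-center haversine distance / conductance; with the
    default inverse-mean-altitude conductance over unit terrain this
    reduces to plain distance, so costs carry meters-like units.
    """
    h = raster.values
    rows, cols = h.shape
    hf = np.maximum(h, spec.altitude_floor)
    lon, lat = raster.cell_centers()
    idx = np.arange(rows * cols).reshape(rows, cols)
    valid = np.isfinite(h)
    cond = spec.conductance()

    src_list, dst_list, cost_list = [], [], []
    # E, S, SE, SW offsets cover all 8 neighbors once (undirected graph)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0 = slice(0, rows - dr)
        r1 = slice(dr, rows)
        c0 = slice(max(0, -dc), cols - max(0, dc))
        c1 = slice(max(0, dc), cols - max(0, -dc))
        ok = valid[r0, c0] & valid[r1, c1]
        if not ok.any():
            continue
        a = idx[r0, c0][ok]
        b = idx[r1, c1][ok]
        dist = haversine_m(
            lon[r0, c0][ok], lat[r0, c0][ok], lon[r1, c1][ok], lat[r1, c1][ok]
        )
        c = cond(hf[r0, c0][ok], hf[r1, c1][ok])
        if np.any(c <= 0):
            raise ArgumentError("conductance function must be strictly positive")
        src_list.append(a)
        dst_list.append(b)
        cost_list.append(dist / c)
    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    cost = np.concatenate(cost_list)
    return coo_matrix((cost, (src, dst)), shape=(rows * cols, rows * cols)).tocsr()


def lcp_distance_matrix(
    samples: SampleSet, raster: Raster, spec: TransitionSpec | None = None
) -> DistanceMatrix:
    """Least-cost-path distances between the cells containing the samples.

    Each sample resolves to the center of its containing cell; sub-cell
    offsets are ignored. Pairs separated by NODATA on every route are
    missing (with a warning). Two samples in the same cell are at
    distance zero.
    """
    spec = spec or TransitionSpec()
    cells = np.array(
        [raster.cell_of(lon, lat) for lon, lat in zip(samples.lon, samples.lat)]
    )
    flat = cells[:, 0] * raster.n_cols + cells[:, 1]
    for k, f in enumerate(flat):
        if not np.isfinite(raster.values.ravel()[f]):
            raise ArgumentError(f"sample {samples.ids[k]!r} falls on a NODATA cell")
    graph = _lcp_graph(raster, spec)
    sources, inverse = np.unique(flat, return_inverse=True)
    dist = dijkstra(graph, directed=False, indices=sources)
    vals = dist[inverse][:, flat]
    vals = np.where(np.isinf(vals), np.nan, vals)
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    if np.isnan(vals).any():
        warnings.warn("some sample pairs are separated by NODATA; entries set missing")
    return DistanceMatrix(list(samples.ids), vals)
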