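"""Synthetic dendritic riverscapes with isolation-by-distance structure.

The generators emulate the inputs a riverscape landscape-genetics study
works from — a multi-basin dendritic river network, an altitude surface
rising toward the headwaters with a ridge between basins, samples
placed on the rivers, and mitochondrial-like sequences whose pairwise
divergence tracks a chosen geographic distance — so the whole analysis
pipeline can be exercised and its parameter recovery tested without any
external data.

The generative model for the sequences is deliberately simple: target
genetic distances are ``α · geographic distance`` perturbed by
multiplicative lognormal noise, a genealogy is built from them by
neighbor joining, and sequences evolve down that tree under an HKY
substitution model using exact per-branch transition probabilities.
Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from scipy.linalg import expm
from shapely import STRtree
from shapely.geometry import LineString

from .core import (
    DistanceMatrix,
    AltitudeRaster,
    RiverNetwork,
    SampleSet,
    _node_key,
    haversine_m,
    haversine_matrix,
)
from .errors import ArgumentError
from .genetics import Alignment, nj_tree, parse_tree
from .geodist import build_river_graph, river_distance_matrix, lcp_distance_matrix

__all__ = [
    "SimulationConfig",
    "gen_river_network",
    "gen_altitude_raster",
    "place_samples",
    "gen_ibd_tree",
    "simulate_sequences",
    "complete_river_distances",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults mirror the scale of a two-basin mitochondrial study:
    40 samples, a 1,066-site alignment, an isolation-by-distance slope
    ``ibd_slope`` (α) of 1e-6 substitutions/site per meter of river
    distance, lognormal distance noise ``noise_sigma`` (σ) of 0.2, and
    an HKY model with κ = 2 and equal base frequencies.
    """

    seed: int = 0
    n_basins: int = 2
    branching_depth: int = 4
    n_samples: int = 40
    ibd_slope: float = 1e-6
    noise_sigma: float = 0.2
    generating_distance: str = "river"
    seq_length: int = 1066
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.ibd_slope < 0 or self.noise_sigma < 0:
            raise ArgumentError("ibd_slope and noise_sigma must be non-negative")
        if self.kappa <= 0:
            raise ArgumentError("kappa must be positive")
        if self.seq_length < 1:
            raise ArgumentError("seq_length must be at least 1")
        if len(self.base_freqs) != 4 or abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ArgumentError("base_freqs must be four probabilities summing to 1")
        if self.generating_distance not in ("river", "euclidean", "lcp"):
            raise ArgumentError("generating_distance must be river, euclidean or lcp")
        if self.n_basins < 1 or self.branching_depth < 0 or self.n_samples < 1:
            raise ArgumentError("counts must be positive (depth may be zero)")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "n_basins": self.n_basins,
            "branching_depth": self.branching_depth, "n_samples": self.n_samples,
            "ibd_slope": self.ibd_slope, "noise_sigma": self.noise_sigma,
            "generating_distance": self.generating_distance,
            "seq_length": self.seq_length, "kappa": self.kappa,
            "base_freqs": list(self.base_freqs),
        }


# ---------------------------------------------------------------------------
# river network
# ---------------------------------------------------------------------------

def gen_river_network(
    n_basins: int,
    branching_depth: int,
    seed: int,
    *,
    trunk_length_deg: float = 0.25,
    length_decay: float = 0.6,
    basin_spacing_deg: float = 0.8,
    origin: tuple[float, float] = (-7.5, 42.0),
) -> RiverNetwork:
    """Grow one planar binary branching tree per basin.

    Each basin starts from an outlet on a common southern baseline and
    grows a trunk northward; every arc of level ℓ < depth spawns two
    children rotated by a random angle, with lengths decaying by
    ``length_decay`` per level so headwaters sit near the divides.
    Basins are laid side by side ``basin_spacing_deg`` apart.
    """
    if n_basins < 1:
        raise ArgumentError("n_basins must be at least 1")
    if branching_depth < 0:
        raise ArgumentError("branching_depth must be non-negative")
    rng = np.random.default_rng(seed)
    arcs: list[np.ndarray] = []
    basins: list[int] = []
    base_heading = math.pi / 2.0  # north

    def grow(start, heading, length, level, basin):
        heading = min(max(heading, base_heading - 1.1), base_heading + 1.1)
        end = (
            start[0] + length * math.cos(heading),
            start[1] + length * math.sin(heading),
        )
        mid = ((start[0] + end[0]) / 2.0, (start[1] + end[1]) / 2.0)
        bend = rng.uniform(-0.08, 0.08) * length
        perp = (math.cos(heading + math.pi / 2.0), math.sin(heading + math.pi / 2.0))
        mid = (mid[0] + bend * perp[0], mid[1] + bend * perp[1])
        arcs.append(np.array([start, mid, end]))
        basins.append(basin)
        if level < branching_depth:
            for sign in (1.0, -1.0):
                dtheta = rng.uniform(0.35, 0.9)
                grow(end, heading + sign * dtheta, length * length_decay, level + 1, basin)

    for b in range(n_basins):
        outlet = (origin[0] + b * basin_spacing_deg, origin[1])
        grow(outlet, base_heading, trunk_length_deg, 0, b)
    return RiverNetwork(arcs, basins)


# ---------------------------------------------------------------------------
# altitude surface
# ---------------------------------------------------------------------------

def _network_distance_fields(net: RiverNetwork):
    """Per-arc outlet distances needed to evaluate the along-network
    distance of any point projected onto an arc."""
    g = net.graph()
    node_dist: dict = {}
    for b, outlet in net.outlet_nodes().items():
        node_dist.update(nx.single_source_dijkstra_path_length(g, outlet, weight="weight"))
    lengths = net.arc_lengths_m()
    d_start = np.array([node_dist[_node_key(*arc[0])] for arc in net.arcs])
    d_end = np.array([node_dist[_node_key(*arc[-1])] for arc in net.arcs])
    return lengths, d_start, d_end


def network_distance_from_outlet(net: RiverNetwork, lon, lat) -> np.ndarray:
    """Along-network distance (m) from the basin outlet to the nearest
    network point of each query location."""
    lon = np.atleast_1d(np.asarray(lon, float))
    lat = np.atleast_1d(np.asarray(lat, float))
    lengths, d_start, d_end = _network_distance_fields(net)
    lines = [LineString(arc) for arc in net.arcs]
    tree = STRtree(lines)
    pts = shapely.points(lon, lat)
    nearest = tree.nearest(pts)
    fracs = np.array(
        [
            shapely.line_locate_point(lines[a], p) / max(lines[a].length, 1e-300)
            for a, p in zip(nearest, pts)
        ]
    )
    pos = fracs * lengths[nearest]
    return np.minimum(
        d_start[nearest] + pos, d_end[nearest] + (lengths[nearest] - pos)
    )


def gen_altitude_raster(
    net: RiverNetwork,
    cell_size: float = 0.02,
    base: float = 200.0,
    gain: float = 0.02,
    *,
    ridge_height: float = 500.0,
    ridge_width_deg: float = 0.12,
) -> AltitudeRaster:
    """Altitude surface rising along the drainage toward headwaters.

    Elevation = ``base`` + ``gain`` × (along-network distance from the
    nearest outlet of the cell's nearest arc, meters) + a Gaussian
    ridge of ``ridge_height`` m centered midway between adjacent basin
    outlets. The grid covers the network bounding box padded by two
    cells.
    """
    if net.n_arcs == 0:
        raise ArgumentError("cannot build a raster for an empty network")
    if cell_size <= 0:
        raise ArgumentError("cell_size must be positive")
    min_lon, min_lat, max_lon, max_lat = net.bounds()
    x0 = min_lon - 2 * cell_size
    y0 = min_lat - 2 * cell_size
    n_cols = int(math.ceil((max_lon - min_lon) / cell_size)) + 4
    n_rows = int(math.ceil((max_lat - min_lat) / cell_size)) + 4

    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    lon = x0 + (cols + 0.5) * cell_size
    lat = y0 + (n_rows - rows - 0.5) * cell_size
    lon_g = np.broadcast_to(lon, (n_rows, n_cols))
    lat_g = np.broadcast_to(lat[:, None], (n_rows, n_cols))

    d_net = network_distance_from_outlet(net, lon_g.ravel(), lat_g.ravel()).reshape(
        n_rows, n_cols
    )
    values = base + gain * d_net

    outlets = net.outlet_nodes()
    if len(outlets) > 1 and ridge_height > 0:
        out_lons = sorted(o[0] for o in outlets.values())
        for left, right in zip(out_lons[:-1], out_lons[1:]):
            mid = (left + right) / 2.0
            values = values + ridge_height * np.exp(
                -(((lon_g - mid) / ridge_width_deg) ** 2)
            )
    return AltitudeRaster(
        origin=(x0, y0), cell_size=cell_size, values=values, floor=min(1.0, base)
    )


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

def place_samples(net: RiverNetwork, n: int, seed: int) -> SampleSet:
    """Draw n sample locations length-uniformly over the whole network.

    Each sample carries the basin label of its arc and is marked as
    already snapped (offset zero, arc position recorded) since it lies
    on the network by construction. Clade labels default to ``"A"``.
    """
    if n < 1:
        raise ArgumentError("n must be at least 1")
    if net.n_arcs == 0:
        raise ArgumentError("cannot place samples on an empty network")
    rng = np.random.default_rng(seed)
    lengths = net.arc_lengths_m()
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    draws = rng.uniform(0.0, cum[-1], size=n)
    arc_idx = np.minimum(np.searchsorted(cum, draws, side="right") - 1, net.n_arcs - 1)
    pos = draws - cum[arc_idx]

    lon = np.empty(n)
    lat = np.empty(n)
    for k in range(n):
        lon[k], lat[k] = _point_along_arc(net.arcs[arc_idx[k]], pos[k])
    return SampleSet(
        ids=[f"s{k:03d}" for k in range(n)],
        lon=lon,
        lat=lat,
        basin=[net.basin_ids[a] for a in arc_idx],
        clade=["A"] * n,
        snap_offset=np.zeros(n),
        arc_index=arc_idx,
        arc_pos_m=pos,
    )


def _point_along_arc(arc: np.ndarray, pos_m: float) -> tuple[float, float]:
    seg = haversine_m(arc[:-1, 0], arc[:-1, 1], arc[1:, 0], arc[1:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    pos_m = float(np.clip(pos_m, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, pos_m, side="right") - 1)
    i = min(i, len(seg) - 1)
    f = 0.0 if seg[i] == 0 else (pos_m - cum[i]) / seg[i]
    return (
        float(arc[i, 0] + f * (arc[i + 1, 0] - arc[i, 0])),
        float(arc[i, 1] + f * (arc[i + 1, 1] - arc[i, 1])),
    )


# ---------------------------------------------------------------------------
# genealogy and sequences
# ---------------------------------------------------------------------------

def gen_ibd_tree(
    geo: DistanceMatrix, ibd_slope: float, noise_sigma: float, seed: int
) -> str:
    """Neighbor-joining genealogy whose patristic distances target
    ``α · geographic distance`` with multiplicative lognormal noise.

    Noise factors ε_ij ~ lognormal(0, σ²) are symmetrized by averaging;
    with σ = 0 and an additive geographic matrix the tree reproduces
    α·geo exactly. Negative NJ branch lengths are clamped to zero.
    """
    if not geo.is_complete():
        raise ArgumentError("generative tree requires a complete geographic matrix")
    if ibd_slope < 0 or noise_sigma < 0:
        raise ArgumentError("slope and noise must be non-negative")
    rng = np.random.default_rng(seed)
    n = geo.n
    eps = rng.lognormal(mean=0.0, sigma=noise_sigma, size=(n, n))
    eps = (eps + eps.T) / 2.0
    target = ibd_slope * geo.values * eps
    np.fill_diagonal(target, 0.0)
    return nj_tree(DistanceMatrix(list(geo.ids), target))


def hky_rate_matrix(kappa: float, base_freqs) -> np.ndarray:
    """HKY85 instantaneous rate matrix (states A, C, G, T), scaled to
    one expected substitution per site per unit branch length."""
    pi = np.asarray(base_freqs, float)
    if len(pi) != 4 or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ArgumentError("base_freqs must be four probabilities summing to 1")
    if kappa <= 0:
        raise ArgumentError("kappa must be positive")
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -float(np.sum(pi * np.diag(q)))
    return q / rate


def simulate_sequences(
    newick: str, seq_length: int, kappa: float, base_freqs, seed: int
) -> Alignment:
    """Evolve sequences down a tree under HKY85.

    The root sequence is drawn site-wise from ``base_freqs``; each site
    then evolves independently along every branch using the exact
    transition matrix ``expm(Q t)`` for that branch length t (expected
    substitutions per site). Returns the tip sequences keyed by label.
    """
    if seq_length < 1:
        raise ArgumentError("seq_length must be at least 1")
    tree = parse_tree(newick)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is not None and edge.length < 0:
            raise ArgumentError("negative branch length in input tree")
    q = hky_rate_matrix(kappa, base_freqs)
    pi = np.asarray(base_freqs, float)
    rng = np.random.default_rng(seed)

    p_cache: dict[float, np.ndarray] = {}

    def pmatrix(t: float) -> np.ndarray:
        if t not in p_cache:
            p_cache[t] = np.cumsum(expm(q * t), axis=1)
        return p_cache[t]

    states: dict = {}
    root = tree.seed_node
    states[root] = rng.choice(4, size=seq_length, p=pi)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent_states = states[node.parent_node]
        if t == 0.0:
            states[node] = parent_states.copy()
        else:
            cum = pmatrix(t)
            u = rng.random(seq_length)
            child = np.empty(seq_length, dtype=np.int64)
            for s in range(4):
                mask = parent_states == s
                if mask.any():
                    child[mask] = np.searchsorted(cum[s], u[mask], side="right")
            states[node] = np.minimum(child, 3)

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    ids, seqs = [], []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label is None:
            raise ArgumentError("tree has unlabelled tips")
        ids.append(label)
        seqs.append(bases[states[leaf]].tobytes().decode("ascii"))
    return Alignment(ids, seqs)


# ---------------------------------------------------------------------------
# generative geographic distances
# ---------------------------------------------------------------------------

def complete_river_distances(samples: SampleSet, net: RiverNetwork) -> DistanceMatrix:
    """River distances completed across basins by joining outlets.

    Within a basin this is the ordinary along-network distance. For a
    pair in different basins — which the analysis side treats as
    missing — the generative model assumes connectivity at the coast:
    d = d(i → outlet of i's basin) + great-circle(outlet_i, outlet_j)
    + d(outlet_j → j). Only used to build synthetic genealogies.
    """
    d = river_distance_matrix(samples, net)
    if d.is_complete():
        return d
    g = build_river_graph(samples, net)
    outlets = net.outlet_nodes()
    lengths_from = {
        b: nx.single_source_dijkstra_path_length(g, node, weight="weight")
        for b, node in outlets.items()
    }
    to_outlet = np.empty(samples.n)
    outlet_of = []
    for k in range(samples.n):
        b = samples.basin[k]
        to_outlet[k] = lengths_from[b][("sample", samples.ids[k])]
        outlet_of.append(outlets[b])
    vals = d.values.copy()
    for i in range(samples.n):
        for j in range(i + 1, samples.n):
            if not np.isfinite(vals[i, j]):
                sea = haversine_m(
                    outlet_of[i][0], outlet_of[i][1], outlet_of[j][0], outlet_of[j][1]
                )
                vals[i, j] = vals[j, i] = to_outlet[i] + float(sea) + to_outlet[j]
    return DistanceMatrix(list(d.ids), vals)


def generating_distance_matrix(
    samples: SampleSet,
    net: RiverNetwork,
    raster: AltitudeRaster,
    which: str,
) -> DistanceMatrix:
    """The complete geographic matrix driving the genetic simulation."""
    if which == "river":
        return complete_river_distances(samples, net)
    if which == "euclidean":
        return haversine_matrix(samples)
    if which == "lcp":
        d = lcp_distance_matrix(samples, raster)
        if not d.is_complete():
            raise ArgumentError("least-cost generating matrix has unreachable pairs")
        return d
    raise ArgumentError("generating distance must be river, euclidean or lcp")
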