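"""Shared containers and geodesy for riverscape analyses.

Conventions used throughout the package:

* coordinates are WGS84 longitude/latitude in decimal degrees;
* all distances are in meters, computed on a sphere of radius
  6,371,000 m (the conventional mean Earth radius), so results are
  bit-reproducible across platforms;
* missing distance-matrix entries (e.g. river distances between
  disconnected basins) are stored as NaN and serialized as ``"NA"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, FormatError

#: Conventional mean Earth radius, meters.
EARTH_RADIUS_M = 6_371_000.0

#: Meters per degree of latitude on the reference sphere.
M_PER_DEG = EARTH_RADIUS_M * math.pi / 180.0

#: Coordinate tolerance (degrees) for matching river-network junctions.
JUNCTION_TOL_DEG = 1e-6


# ---------------------------------------------------------------------------
# geodesy
# ---------------------------------------------------------------------------

def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in meters between points in degrees.

    Accepts scalars or broadcastable arrays. Latitudes must lie in
    [-90, 90] and longitudes in [-180, 180].
    """
    lon1, lat1, lon2, lat2 = (np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ArgumentError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ArgumentError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def polyline_length_m(coords: np.ndarray) -> float:
    """Summed haversine length of a (k, 2) lon/lat polyline."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        return 0.0
    return float(
        np.sum(haversine_m(coords[:-1, 0], coords[:-1, 1], coords[1:, 0], coords[1:, 1]))
    )


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with an id order.

    ``values`` is an (n, n) float array; NaN marks a missing entry
    (both of the mirrored cells). The diagonal is zero and no finite
    entry is negative.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ArgumentError("duplicate ids in distance matrix")
        if self.values.shape != (n, n):
            raise ArgumentError(
                f"distance matrix shape {self.values.shape} does not match {n} ids"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ArgumentError("negative distance entry")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ArgumentError("nonzero diagonal in distance matrix")
        finite = np.isfinite(self.values)
        if not np.array_equal(finite, finite.T):
            raise ArgumentError("asymmetric missingness pattern")
        if not np.allclose(
            self.values[finite], self.values.T[finite], rtol=1e-9, atol=0.0
        ):
            raise ArgumentError("distance matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    def index_of(self, sample_id: str) -> int:
        return self.ids.index(sample_id)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index_of(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)].copy())

    def reordered(self, ids: Sequence[str]) -> "DistanceMatrix":
        if set(ids) != set(self.ids):
            raise ArgumentError("reordering ids must be a permutation of matrix ids")
        return self.submatrix(ids)

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.index.name = "id"
        df.to_csv(path, na_rep="NA", float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col="id", na_values=["NA"])
        ids = [str(i) for i in df.index]
        if ids != [str(c) for c in df.columns]:
            raise FormatError("distance matrix CSV row/column ids differ")
        return cls(ids, df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# SampleSet
# ---------------------------------------------------------------------------

@dataclass
class SampleSet:
    """Georeferenced, labelled specimens.

    ``basin``/``clade`` may be ``None`` for unknown labels. After
    :func:`riverscape.geodist.snap_to_network` the ``snap_offset``
    column records the meters each point moved and ``arc_index`` /
    ``arc_pos_m`` locate the point on the network (arc number and
    distance in meters along the arc from its first vertex).
    """

    ids: list[str]
    lon: np.ndarray
    lat: np.ndarray
    basin: list
    clade: list
    snap_offset: np.ndarray | None = None
    arc_index: np.ndarray | None = None
    arc_pos_m: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ArgumentError("duplicate sample ids")
        if self.lon.shape != (n,) or self.lat.shape != (n,):
            raise ArgumentError("coordinate arrays must match number of ids")
        if np.any(np.abs(self.lon) > 180) or np.any(np.abs(self.lat) > 90):
            raise ArgumentError("coordinates outside valid lon/lat ranges")
        if len(self.basin) != n or len(self.clade) != n:
            raise ArgumentError("label lists must match number of ids")
        if self.snap_offset is None:
            self.snap_offset = np.zeros(n)
        else:
            self.snap_offset = np.asarray(self.snap_offset, dtype=float)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_snapped(self) -> bool:
        return self.arc_index is not None

    def subset(self, keep: Sequence[int]) -> "SampleSet":
        keep = list(keep)
        return SampleSet(
            ids=[self.ids[i] for i in keep],
            lon=self.lon[keep],
            lat=self.lat[keep],
            basin=[self.basin[i] for i in keep],
            clade=[self.clade[i] for i in keep],
            snap_offset=self.snap_offset[keep],
            arc_index=None if self.arc_index is None else self.arc_index[keep],
            arc_pos_m=None if self.arc_pos_m is None else self.arc_pos_m[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "lon": self.lon,
                "lat": self.lat,
                "basin": self.basin,
                "clade": self.clade,
                "snap_offset": self.snap_offset,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSet":
        df = pd.read_csv(path, na_values=["NA"], dtype={"id": str})
        for col in ("id", "lon", "lat"):
            if col not in df.columns:
                raise FormatError(f"sample CSV missing required column {col!r}")
        basin = df["basin"].tolist() if "basin" in df.columns else [None] * len(df)
        clade = df["clade"].tolist() if "clade" in df.columns else [None] * len(df)
        basin = [None if (isinstance(b, float) and math.isnan(b)) else b for b in basin]
        clade = [None if (isinstance(c, float) and math.isnan(c)) else c for c in clade]
        return cls(
            ids=df["id"].tolist(),
            lon=df["lon"].to_numpy(float),
            lat=df["lat"].to_numpy(float),
            basin=basin,
            clade=clade,
        )


def haversine_matrix(samples: SampleSet) -> DistanceMatrix:
    """All-pairs great-circle distance matrix (meters) for a sample set."""
    lon, lat = samples.lon, samples.lat
    d = haversine_m(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(samples.ids), d)


# ---------------------------------------------------------------------------
# RiverNetwork
# ---------------------------------------------------------------------------

def _node_key(lon: float, lat: float) -> tuple[float, float]:
    # quantize to the junction tolerance so shared endpoints coincide
    return (round(lon, 6), round(lat, 6))


@dataclass
class RiverNetwork:
    """Polyline arcs forming one tree-shaped component per basin.

    ``arcs[k]`` is a (m_k, 2) array of lon/lat vertices; ``basin_ids[k]``
    is the integer drainage-basin label of arc k.
    """

    arcs: list[np.ndarray]
    basin_ids: list[int]

    def __post_init__(self) -> None:
        self.arcs = [np.asarray(a, dtype=float) for a in self.arcs]
        for a in self.arcs:
            if a.ndim != 2 or a.shape[1] != 2 or len(a) < 2:
                raise ArgumentError("each arc must be a (k>=2, 2) lon/lat polyline")
        if len(self.basin_ids) != len(self.arcs):
            raise ArgumentError("basin_ids must match number of arcs")
        self.basin_ids = [int(b) for b in self.basin_ids]

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def arc_lengths_m(self) -> np.ndarray:
        return np.array([polyline_length_m(a) for a in self.arcs])

    def total_length_m(self) -> float:
        return float(self.arc_lengths_m().sum())

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) over all vertices."""
        allv = np.vstack(self.arcs)
        return (
            float(allv[:, 0].min()),
            float(allv[:, 1].min()),
            float(allv[:, 0].max()),
            float(allv[:, 1].max()),
        )

    def graph(self):
        """Arc-endpoint graph: nodes are quantized endpoints, one edge
        per arc weighted by its haversine length (meters)."""
        import networkx as nx

        g = nx.Graph()
        for k, arc in enumerate(self.arcs):
            u = _node_key(*arc[0])
            v = _node_key(*arc[-1])
            g.add_edge(u, v, weight=polyline_length_m(arc), arc=k, basin=self.basin_ids[k])
        return g

    def outlet_nodes(self) -> dict[int, tuple[float, float]]:
        """Per basin, the southernmost endpoint node (the network is
        assumed to drain southward, as the synthetic generator builds it;
        for real data the outlet only matters to the synthetic elevation
        model)."""
        outlets: dict[int, tuple[float, float]] = {}
        for k, arc in enumerate(self.arcs):
            b = self.basin_ids[k]
            for endpoint in (arc[0], arc[-1]):
                key = _node_key(*endpoint)
                if b not in outlets or key[1] < outlets[b][1]:
                    outlets[b] = key
        return outlets

    # -- serialization ------------------------------------------------------

    def to_geojson(self, path: str | Path | None = None) -> dict:
        obj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"basin_id": b},
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[round(x, 8), round(y, 8)] for x, y in arc],
                    },
                }
                for arc, b in zip(self.arcs, self.basin_ids)
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj))
        return obj

    @classmethod
    def from_geojson(cls, src: str | Path | dict) -> "RiverNetwork":
        if isinstance(src, (str, Path)):
            obj = json.loads(Path(src).read_text())
        else:
            obj = src
        if obj.get("type") != "FeatureCollection":
            raise FormatError("expected a GeoJSON FeatureCollection")
        arcs, basins = [], []
        for feat in obj.get("features", []):
            geom = feat.get("geometry", {})
            if geom.get("type") != "LineString":
                raise FormatError("network features must be LineStrings")
            arcs.append(np.asarray(geom["coordinates"], dtype=float))
            props = feat.get("properties") or {}
            basins.append(props.get("basin_id", -1))
        net = cls(arcs, basins)
        if any(b == -1 for b in net.basin_ids):
            net.basin_ids = _infer_basins(net)
        return net


def _infer_basins(net: RiverNetwork) -> list[int]:
    """Label arcs by connected component when basin_id is absent."""
    import networkx as nx

    g = net.graph()
    comp_of = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_of[node] = i
    return [comp_of[_node_key(*arc[0])] for arc in net.arcs]


# ---------------------------------------------------------------------------
# Rasters (ESRI ASCII grid)
# ---------------------------------------------------------------------------

@dataclass
class Raster:
    """Regular lon/lat grid.

    ``origin`` is the lower-left corner (xllcorner, yllcorner) in
    degrees; ``values`` is (n_rows, n_cols) row-major from the top,
    matching the ESRI ASCII grid layout. NaN entries are NODATA.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ArgumentError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ArgumentError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Lon/lat of the center of cell (row, col); row 0 is the top row."""
        x0, y0 = self.origin
        lon = x0 + (col + 0.5) * self.cell_size
        lat = y0 + (self.n_rows - row - 0.5) * self.cell_size
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        x0, y0 = self.origin
        col = int(math.floor((lon - x0) / self.cell_size))
        row_from_bottom = int(math.floor((lat - y0) / self.cell_size))
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ArgumentError(f"point ({lon}, {lat}) falls outside the raster extent")
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (n_rows, n_cols) of cell-center lon and lat."""
        rows = np.arange(self.n_rows)
        cols = np.arange(self.n_cols)
        x0, y0 = self.origin
        lon = x0 + (cols + 0.5) * self.cell_size
        lat = y0 + (self.n_rows - rows - 0.5) * self.cell_size
        return np.broadcast_to(lon, (self.n_rows, self.n_cols)).copy(), np.broadcast_to(
            lat[:, None], (self.n_rows, self.n_cols)
        ).copy()

    def to_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        vals = np.where(np.isfinite(self.values), self.values, nodata)
        header = (
            f"NCOLS {self.n_cols}\n"
            f"NROWS {self.n_rows}\n"
            f"XLLCORNER {self.origin[0]:.10g}\n"
            f"YLLCORNER {self.origin[1]:.10g}\n"
            f"CELLSIZE {self.cell_size:.10g}\n"
            f"NODATA_VALUE {nodata:.10g}\n"
        )
        body = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in vals)
        Path(path).write_text(header + body + "\n")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "Raster":
        lines = Path(path).read_text().splitlines()
        header: dict[str, float] = {}
        body_start = 0
        for i, line in enumerate(lines):
            parts = line.split()
            if len(parts) == 2 and parts[0].upper() in {
                "NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE", "NODATA_VALUE",
            }:
                header[parts[0].upper()] = float(parts[1])
                body_start = i + 1
            else:
                break
        for key in ("NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE"):
            if key not in header:
                raise FormatError(f"ESRI ASCII grid missing header field {key}")
        vals = np.loadtxt(lines[body_start:], dtype=float, ndmin=2)
        if vals.shape != (int(header["NROWS"]), int(header["NCOLS"])):
            raise FormatError("ESRI ASCII grid body does not match declared dimensions")
        nodata = header.get("NODATA_VALUE")
        if nodata is not None:
            vals = np.where(vals == nodata, np.nan, vals)
        return cls(
            origin=(header["XLLCORNER"], header["YLLCORNER"]),
            cell_size=header["CELLSIZE"],
            values=vals,
        )


@dataclass
class AltitudeRaster(Raster):
    """Elevation grid in meters; all values finite and above a floor."""

    floor: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.values)):
            raise ArgumentError("altitude raster must be fully finite")
        if np.any(self.values < self.floor):
            raise ArgumentError(f"altitude below configured floor {self.floor}")


@dataclass
class DiversityGrid(Raster):
    """Interpolated nucleotide-diversity surface plus the IDW exponent."""

    power: float = 2.0
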