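import numpy as np
import pytest

from riverscape.core import M_PER_DEG, RiverNetwork, SampleSet


def meridian_arc(lon: float, lat0: float, length_m: float, n_vertices: int = 5) -> np.ndarray:
    """Straight south→north polyline of a given haversine length."""
    dlat = length_m / M_PER_DEG
    lats = np.linspace(lat0, lat0 + dlat, n_vertices)
    return np.column_stack((np.full(n_vertices, lon), lats))


@pytest.fixture
def straight_network() -> RiverNetwork:
    """Single 10 km meridian arc, one basin."""
    return RiverNetwork([meridian_arc(-7.0, 42.0, 10_000.0)], [0])


@pytest.fixture
def two_basin_network() -> RiverNetwork:
    """Two disjoint meridian arcs of equal length in separate basins."""
    return RiverNetwork(
        [meridian_arc(-7.0, 42.0, 10_000.0), meridian_arc(-6.5, 42.0, 10_000.0)],
        [0, 1],
    )


@pytest.fixture
def y_network() -> RiverNetwork:
    """A trunk splitting into two branches at a junction."""
    trunk = meridian_arc(-7.0, 42.0, 5_000.0)
    junction = trunk[-1]
    dlat = 4_000.0 / M_PER_DEG
    dlon = 3_000.0 / (M_PER_DEG * np.cos(np.radians(junction[1])))
    left = np.array([junction, [junction[0] - dlon, junction[1] + dlat]])
    right = np.array([junction, [junction[0] + dlon, junction[1] + dlat]])
    return RiverNetwork([trunk, left, right], [0, 0, 0])


def samples_on_meridian(lon: float, lat0: float, offsets_m, ids=None) -> SampleSet:
    offsets_m = np.asarray(offsets_m, dtype=float)
    n = len(offsets_m)
    return SampleSet(
        ids=ids or [f"p{k}" for k in range(n)],
        lon=np.full(n, lon),
        lat=lat0 + offsets_m / M_PER_DEG,
        basin=[0] * n,
        clade=["A"] * n,
    )
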