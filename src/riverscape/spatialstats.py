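"""Inferential statistics for riverscape isolation by distance.

* a missing-aware Mantel permutation test (two-tailed, add-one
  smoothed, so the smallest attainable p at 9,999 permutations is
  2/10,000 = .0002);
* a one-way distance-matrix AMOVA with Φ_ST and a label-permutation
  p-value;
* spatially windowed nucleotide diversity (all samples within a fixed
  great-circle radius of each sampling point);
* inverse-distance-weighted interpolation of point values onto a grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    M_PER_DEG,
    DistanceMatrix,
    DiversityGrid,
    SampleSet,
    haversine_m,
)
from .errors import ArgumentError, ComputationError
from .genetics import Alignment, nucleotide_diversity

_TOL = 1e-12


@dataclass
class MantelResult:
    """Observed matrix correlation and its permutation p-value."""

    r: float
    p: float
    n_perm: int
    n_pairs_used: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_perm": self.n_perm,
                "n_pairs_used": self.n_pairs_used}


@dataclass
class AmovaResult:
    """One-way AMOVA decomposition of squared pairwise distances.

    ``sigma2_a`` is the among-group variance component (not truncated
    at zero), ``sigma2_w`` the within-group component, ``phi_st`` their
    among fraction, and ``pct_among`` = 100·Φ_ST.
    """

    ssd_among: float
    ssd_within: float
    ssd_total: float
    df_among: int
    df_within: int
    msd_among: float
    msd_within: float
    n_eff: float
    sigma2_a: float
    sigma2_w: float
    phi_st: float
    pct_among: float
    p: float
    n_perm: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return math.nan
    return float(xc @ yc) / (sx * sy)


def mantel_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel permutation test of correlation between two distance matrices.

    The statistic is the Pearson correlation over the off-diagonal
    upper-triangle pairs that are non-missing in both matrices. Each
    permutation relabels B's rows and columns jointly — missing entries
    travel with the permutation and the set of valid pairs is
    recomputed — and the two-tailed p-value is add-one smoothed:
    ``p = min(1, 2·min(#{r* ≥ r}+1, #{r* ≤ r}+1)/(n_perm+1))``.

    With ``exhaustive=True`` all n! relabelings are enumerated (identity
    included) and ``p = min(1, 2·min(#ge, #le)/n!)``; only sensible for
    small n.
    """
    if A.ids != B.ids:
        raise ArgumentError("Mantel test requires matrices with identical id order")
    n = A.n
    if n < 4:
        raise ArgumentError("Mantel test requires at least four samples")
    iu = np.triu_indices(n, k=1)
    a_full = A.values[iu]
    b_full = B.values[iu]
    valid = np.isfinite(a_full) & np.isfinite(b_full)
    if valid.sum() < 3:
        raise ArgumentError("fewer than three valid (non-missing) pairs")
    r_obs = _pearson(a_full[valid], b_full[valid])
    if math.isnan(r_obs):
        raise ComputationError("zero variance among valid pairs of a matrix")

    Bv = B.values

    def perm_r(p: np.ndarray) -> float:
        bp = Bv[np.ix_(p, p)][iu]
        ok = np.isfinite(a_full) & np.isfinite(bp)
        if ok.sum() < 3:
            return math.nan
        return _pearson(a_full[ok], bp[ok])

    if exhaustive:
        rs = np.array([perm_r(np.array(p)) for p in itertools.permutations(range(n))])
        total = len(rs)
        ge = int(np.sum(rs >= r_obs - _TOL))
        le = int(np.sum(rs <= r_obs + _TOL))
        p_val = min(1.0, 2.0 * min(ge, le) / total)
        return MantelResult(r_obs, p_val, total, int(valid.sum()))

    rng = np.random.default_rng(seed)
    rs = np.empty(n_perm)
    for k in range(n_perm):
        rs[k] = perm_r(rng.permutation(n))
    with np.errstate(invalid="ignore"):
        ge = int(np.sum(rs >= r_obs - _TOL))
        le = int(np.sum(rs <= r_obs + _TOL))
    p_val = min(1.0, 2.0 * min(ge + 1, le + 1) / (n_perm + 1))
    return MantelResult(r_obs, p_val, n_perm, int(valid.sum()))


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _amova_ssd(D2: np.ndarray, group_indices: list[np.ndarray]) -> tuple[float, float]:
    """(SSD_total, SSD_within) from squared distances and group index sets."""
    n = D2.shape[0]
    ssd_total = float(np.triu(D2, k=1).sum()) / n
    ssd_within = 0.0
    for idx in group_indices:
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ssd_within += float(np.triu(sub, k=1).sum()) / len(idx)
    return ssd_total, ssd_within


def amova_oneway(
    d: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """One-way AMOVA on a complete pairwise distance matrix.

    Decomposes SSD_total = (1/N)·Σ_{i<j} d²_ij into within-group sums
    (1/n_g)·Σ_{i<j∈g} d²_ij and an among-group remainder; variance
    components follow from the mean squares with the unequal-group-size
    coefficient n′ = (N − Σ n_g²/N)/(G−1). The p-value permutes group
    labels and counts Φ* ≥ Φ with add-one smoothing.
    """
    if not d.is_complete():
        raise ArgumentError(
            "AMOVA requires a complete matrix (river matrices with missing "
            "inter-basin pairs are not valid input)"
        )
    groups = list(groups)
    if len(groups) != d.n:
        raise ArgumentError("one group label per matrix id is required")
    labels = sorted(set(groups), key=str)
    if len(labels) < 2:
        raise ArgumentError("AMOVA requires at least two groups")
    N, G = d.n, len(labels)
    if N <= G:
        raise ArgumentError("AMOVA requires more samples than groups")

    D2 = d.values**2
    garr = np.array([labels.index(g) for g in groups])

    def decompose(assign: np.ndarray):
        idx_sets = [np.flatnonzero(assign == k) for k in range(G)]
        ssd_total, ssd_within = _amova_ssd(D2, idx_sets)
        ssd_among = ssd_total - ssd_within
        df_among, df_within = G - 1, N - G
        msd_among = ssd_among / df_among
        msd_within = ssd_within / df_within
        sizes = np.array([len(s) for s in idx_sets])
        n_eff = (N - float(np.sum(sizes**2)) / N) / (G - 1)
        sigma2_w = msd_within
        sigma2_a = (msd_among - msd_within) / n_eff
        denom = sigma2_a + sigma2_w
        phi = sigma2_a / denom if denom != 0 else math.nan
        return (ssd_among, ssd_within, ssd_total, df_among, df_within,
                msd_among, msd_within, n_eff, sigma2_a, sigma2_w, phi)

    obs = decompose(garr)
    phi_obs = obs[10]
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        phi_star = decompose(rng.permutation(garr))[10]
        if not math.isnan(phi_star) and phi_star >= phi_obs - _TOL:
            ge += 1
    p_val = (ge + 1) / (n_perm + 1)
    return AmovaResult(
        ssd_among=obs[0], ssd_within=obs[1], ssd_total=obs[2],
        df_among=obs[3], df_within=obs[4],
        msd_among=obs[5], msd_within=obs[6],
        n_eff=obs[7], sigma2_a=obs[8], sigma2_w=obs[9],
        phi_st=phi_obs, pct_among=100.0 * phi_obs,
        p=p_val, n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# windowed diversity and IDW interpolation
# ---------------------------------------------------------------------------

def windowed_diversity(
    aln: Alignment,
    samples: SampleSet,
    radius_m: float = 10_000.0,
    deletion: str = "pairwise",
) -> np.ndarray:
    """Per-sample nucleotide diversity over a great-circle window.

    For each sampling point the window holds every sample (the focal
    one included) within ``radius_m``; the value is π over the window's
    sequences, or NaN when the window has fewer than two samples.
    """
    if list(aln.ids) != list(samples.ids):
        raise ArgumentError("alignment and sample ids must align")
    if radius_m < 0:
        raise ArgumentError("radius must be non-negative")
    n = samples.n
    dmat = haversine_m(
        samples.lon[:, None], samples.lat[:, None],
        samples.lon[None, :], samples.lat[None, :],
    )
    out = np.full(n, np.nan)
    cache: dict[tuple, float] = {}
    for k in range(n):
        members = tuple(np.flatnonzero(dmat[k] <= radius_m))
        if len(members) < 2:
            continue
        if members not in cache:
            sub = Alignment(
                [aln.ids[i] for i in members], [aln.seqs[i] for i in members]
            )
            cache[members] = nucleotide_diversity(sub, deletion=deletion)
        out[k] = cache[members]
    return out


def idw_interpolate(
    lon: np.ndarray,
    lat: np.ndarray,
    values: np.ndarray,
    grid_cell_m: float = 1000.0,
    power: float = 2.0,
    extent: tuple[float, float, float, float] | None = None,
) -> DiversityGrid:
    """Inverse-distance-weighted interpolation onto a regular grid.

    Cells are square in degrees with side ``grid_cell_m`` divided by the
    meters-per-degree-of-latitude constant (a local-equirectangular
    1 km lattice at the default). Cell value = Σ v_i·d_i^-power /
    Σ d_i^-power with d_i the haversine distance from the cell center;
    a point within 1 m of a center contributes its value exactly.
    Missing point values are excluded.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    values = np.asarray(values, float)
    if power <= 0:
        raise ArgumentError("IDW power must be positive")
    keep = np.isfinite(values)
    if not keep.any():
        raise ArgumentError("IDW needs at least one non-missing point value")
    lon, lat, values = lon[keep], lat[keep], values[keep]
    cell_deg = grid_cell_m / M_PER_DEG
    if extent is None:
        extent = (
            lon.min() - cell_deg, lat.min() - cell_deg,
            lon.max() + cell_deg, lat.max() + cell_deg,
        )
    x0, y0, x1, y1 = extent
    n_cols = max(1, int(math.ceil((x1 - x0) / cell_deg)))
    n_rows = max(1, int(math.ceil((y1 - y0) / cell_deg)))
    grid = np.empty((n_rows, n_cols))
    col_lon = x0 + (np.arange(n_cols) + 0.5) * cell_deg
    for r in range(n_rows):
        clat = y0 + (n_rows - r - 0.5) * cell_deg
        d = haversine_m(col_lon[:, None], clat, lon[None, :], lat[None, :])
        hit = d < 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            w = d ** (-power)
            row_vals = (w * values[None, :]).sum(axis=1) / w.sum(axis=1)
        exact = hit.any(axis=1)
        if exact.any():
            first_hit = np.argmax(hit, axis=1)
            row_vals[exact] = values[first_hit[exact]]
        grid[r] = row_vals
    return DiversityGrid(origin=(x0, y0), cell_size=cell_deg, values=grid, power=power)
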