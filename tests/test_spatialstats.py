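import itertools
import math

import numpy as np
import pytest
from scipy import stats

from riverscape.core import M_PER_DEG, DistanceMatrix, SampleSet, haversine_matrix
from riverscape.errors import ArgumentError, ComputationError
from riverscape.genetics import Alignment, nucleotide_diversity
from riverscape.spatialstats import (
    amova_oneway,
    idw_interpolate,
    mantel_test,
    windowed_diversity,
)

from conftest import samples_on_meridian


def _random_dm(rng, n, ids=None):
    pts = rng.uniform(0, 100, size=(n, 2))
    vals = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix(ids or [f"s{k}" for k in range(n)], vals)


def _exhaustive_oracle(A, B):
    """Exact two-tailed Mantel p by full enumeration, using scipy's
    Pearson correlation (independent of the package's statistic code)."""
    n = A.n
    iu = np.triu_indices(n, k=1)
    a = A.values[iu]
    r_obs = stats.pearsonr(a, B.values[iu]).statistic
    ge = le = 0
    for p in itertools.permutations(range(n)):
        p = np.array(p)
        r = stats.pearsonr(a, B.values[np.ix_(p, p)][iu]).statistic
        ge += r >= r_obs - 1e-12
        le += r <= r_obs + 1e-12
    return r_obs, min(1.0, 2.0 * min(ge, le) / math.factorial(n))


class TestMantel:
    def test_self_correlation_is_one(self):
        d = _random_dm(np.random.default_rng(0), 8)
        res = mantel_test(d, d, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        A = _random_dm(rng, 4)
        B = _random_dm(rng, 4, ids=A.ids)
        res = mantel_test(A, B, exhaustive=True)
        r_exp, p_exp = _exhaustive_oracle(A, B)
        assert res.r == pytest.approx(r_exp)
        assert res.p == pytest.approx(p_exp)
        assert res.n_perm == math.factorial(4)

    @pytest.mark.parametrize("n", [5, 6])
    def test_sampled_p_converges_to_exhaustive(self, n):
        rng = np.random.default_rng(n)
        A = _random_dm(rng, n)
        B = _random_dm(rng, n, ids=A.ids)
        p_exact = mantel_test(A, B, exhaustive=True).p
        n_perm = 4999
        p_sampled = mantel_test(A, B, n_perm=n_perm, seed=11).p
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        # two-tailed doubling at most doubles the Monte-Carlo error
        assert abs(p_sampled - p_exact) <= 3 * 2 * se + 2 / (n_perm + 1)

    def test_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(2)
        A = _random_dm(rng, 7)
        B = _random_dm(rng, 7, ids=A.ids)
        r0 = mantel_test(A, B, n_perm=9, seed=0).r
        perm = rng.permutation(7)
        ids2 = [A.ids[k] for k in perm]
        A2 = A.submatrix(ids2)
        B2 = B.submatrix(ids2)
        r1 = mantel_test(A2, B2, n_perm=9, seed=0).r
        assert r1 == pytest.approx(r0)

    def test_missing_pairs_travel_with_permutation(self):
        rng = np.random.default_rng(3)
        A = _random_dm(rng, 6)
        vals = _random_dm(rng, 6, ids=A.ids).values.copy()
        vals[0, 1] = vals[1, 0] = np.nan
        B = DistanceMatrix(A.ids, vals)
        res = mantel_test(A, B, n_perm=99, seed=0)
        assert res.n_pairs_used == 14  # 15 upper-triangle pairs minus 1 missing
        assert -1.0 <= res.r <= 1.0
        assert 2 / 100 <= res.p <= 1.0

    def test_zero_variance_rejected(self):
        ids = list("abcd")
        A = _random_dm(np.random.default_rng(1), 4, ids=ids)
        B = DistanceMatrix(ids, np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ComputationError):
            mantel_test(A, B, n_perm=9, seed=0)

    def test_id_order_mismatch_rejected(self):
        A = _random_dm(np.random.default_rng(1), 5)
        B = _random_dm(np.random.default_rng(2), 5, ids=A.ids[::-1])
        with pytest.raises(ArgumentError):
            mantel_test(A, B, n_perm=9, seed=0)

    def test_null_pvalues_uniform(self):
        # under an exchangeable null the permutation p-value is uniform
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(500):
            A = _random_dm(rng, 10)
            B = _random_dm(rng, 10, ids=A.ids)
            pvals.append(mantel_test(A, B, n_perm=199, seed=int(rng.integers(2**31))).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def _amova_oracle(vals, groups):
    """Spreadsheet-style sums of squares computed with direct loops."""
    n = len(groups)
    labels = sorted(set(groups))
    ssd_total = sum(vals[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ssd_within = 0.0
    for g in labels:
        idx = [i for i in range(n) if groups[i] == g]
        ssd_within += sum(
            vals[i][j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ssd_among = ssd_total - ssd_within
    G = len(labels)
    msd_among = ssd_among / (G - 1)
    msd_within = ssd_within / (n - G)
    sizes = [sum(1 for x in groups if x == g) for g in labels]
    n_eff = (n - sum(s**2 for s in sizes) / n) / (G - 1)
    sigma2_w = msd_within
    sigma2_a = (msd_among - msd_within) / n_eff
    phi = sigma2_a / (sigma2_a + sigma2_w)
    return dict(ssd_among=ssd_among, ssd_within=ssd_within, ssd_total=ssd_total,
                msd_among=msd_among, msd_within=msd_within, n_eff=n_eff,
                sigma2_a=sigma2_a, sigma2_w=sigma2_w, phi_st=phi)


class TestAmova:
    def test_complete_separation(self):
        ids = list("abcdef")
        vals = np.ones((6, 6))
        vals[:3, :3] = 0.0
        vals[3:, 3:] = 0.0
        d = DistanceMatrix(ids, vals)
        res = amova_oneway(d, ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)

    def test_fields_match_hand_computed_oracle(self):
        ids = list("abcdef")
        vals = np.array([
            [0, 1, 2, 5, 6, 7],
            [1, 0, 1, 6, 5, 6],
            [2, 1, 0, 7, 6, 5],
            [5, 6, 7, 0, 2, 1],
            [6, 5, 6, 2, 0, 3],
            [7, 6, 5, 1, 3, 0],
        ], float)
        groups = ["g1"] * 3 + ["g2"] * 3
        res = amova_oneway(DistanceMatrix(ids, vals), groups, n_perm=99, seed=0)
        exp = _amova_oracle(vals, groups)
        for k, v in exp.items():
            assert getattr(res, k) == pytest.approx(v, rel=1e-12), k
        assert res.df_among == 1 and res.df_within == 4
        # SSD conservation
        assert res.ssd_among + res.ssd_within == pytest.approx(res.ssd_total, rel=1e-9)

    def test_unbalanced_groups_against_oracle(self):
        rng = np.random.default_rng(9)
        d = _random_dm(rng, 9)
        groups = ["a"] * 2 + ["b"] * 3 + ["c"] * 4
        res = amova_oneway(d, groups, n_perm=49, seed=0)
        exp = _amova_oracle(d.values, groups)
        assert res.phi_st == pytest.approx(exp["phi_st"], rel=1e-12)
        assert res.n_eff == pytest.approx(exp["n_eff"], rel=1e-12)

    def test_pct_among_scale_invariant(self):
        rng = np.random.default_rng(4)
        d = _random_dm(rng, 8)
        groups = ["x"] * 4 + ["y"] * 4
        base = amova_oneway(d, groups, n_perm=19, seed=0).pct_among
        scaled = amova_oneway(DistanceMatrix(d.ids, 3.5 * d.values), groups,
                              n_perm=19, seed=0).pct_among
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_type_one_error_controlled_on_exchangeable_data(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            d = _random_dm(rng, 12)
            groups = list(rng.permutation(["u"] * 6 + ["v"] * 6))
            p = amova_oneway(d, groups, n_perm=999, seed=s).p
            hits += p > 0.05
        assert hits >= int(0.9 * n_seeds)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(500):
            d = _random_dm(rng, 16)
            groups = list(rng.permutation(["u"] * 8 + ["v"] * 8))
            pvals.append(amova_oneway(d, groups, n_perm=199,
                                      seed=int(rng.integers(2**31))).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_entries_rejected(self):
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = np.nan
        d = DistanceMatrix(list("abcd"), vals)
        with pytest.raises(ArgumentError):
            amova_oneway(d, ["x", "x", "y", "y"], n_perm=9, seed=0)

    def test_single_group_rejected(self):
        d = _random_dm(np.random.default_rng(1), 5)
        with pytest.raises(ArgumentError):
            amova_oneway(d, ["g"] * 5, n_perm=9, seed=0)


class TestWindowedDiversity:
    def test_isolated_point_is_missing(self):
        s = samples_on_meridian(-7.0, 42.0, [0.0, 50_000.0, 52_000.0])
        aln = Alignment(s.ids, ["AAAA", "AATT", "ATTT"])
        pi = windowed_diversity(aln, s, radius_m=10_000.0)
        assert math.isnan(pi[0])
        assert np.isfinite(pi[1]) and np.isfinite(pi[2])

    def test_shared_window_gives_equal_values(self):
        s = samples_on_meridian(-7.0, 42.0, [0.0, 5_000.0])
        aln = Alignment(s.ids, ["AAAA", "AATT"])
        pi = windowed_diversity(aln, s, radius_m=10_000.0)
        assert pi[0] == pi[1] == pytest.approx(0.5)

    def test_line_of_three_matches_direct_recomputation(self):
        s = samples_on_meridian(-7.0, 42.0, [0.0, 8_000.0, 16_000.0])
        seqs = ["AAAA", "AATT", "ATTT"]
        aln = Alignment(s.ids, seqs)
        pi = windowed_diversity(aln, s, radius_m=10_000.0)
        # end windows hold 2 samples, the middle window all 3
        assert pi[0] == pytest.approx(nucleotide_diversity(Alignment(s.ids[:2], seqs[:2])))
        assert pi[1] == pytest.approx(nucleotide_diversity(aln))
        assert pi[2] == pytest.approx(nucleotide_diversity(Alignment(s.ids[1:], seqs[1:])))


class TestIdw:
    def test_constant_field_everywhere(self):
        s = samples_on_meridian(-7.0, 42.0, [0.0, 3_000.0, 9_000.0])
        grid = idw_interpolate(s.lon, s.lat, np.full(3, 0.125), grid_cell_m=1000.0)
        np.testing.assert_allclose(grid.values, 0.125)

    def test_exact_hit_returns_sample_value(self):
        cell_deg = 1000.0 / M_PER_DEG
        # put one sample exactly on a cell center of the default lattice
        lon = np.array([-7.0 + 0.5 * cell_deg, -7.0 + 5.5 * cell_deg])
        lat = np.array([42.0 + 1.5 * cell_deg, 42.0 + 1.5 * cell_deg])
        grid = idw_interpolate(lon, lat, np.array([0.7, 0.1]), grid_cell_m=1000.0,
                               extent=(-7.0, 42.0, -7.0 + 8 * cell_deg, 42.0 + 3 * cell_deg))
        row, col = grid.cell_of(lon[0], lat[0])
        assert grid.values[row, col] == pytest.approx(0.7)

    def test_equidistant_cell_averages_symmetric_values(self):
        cell_deg = 1000.0 / M_PER_DEG
        lat_mid = 42.0 + 1.5 * cell_deg
        # samples at the centers of columns 0 and 2 of row 1: the center
        # of column 1 is equidistant from both
        lon = np.array([-7.0 + 0.5 * cell_deg, -7.0 + 2.5 * cell_deg])
        lat = np.array([lat_mid, lat_mid])
        grid = idw_interpolate(lon, lat, np.array([0.0, 1.0]), grid_cell_m=1000.0,
                               extent=(-7.0, 42.0, -7.0 + 3 * cell_deg, 42.0 + 3 * cell_deg))
        row, col = grid.cell_of(-7.0 + 1.5 * cell_deg, lat_mid)
        assert grid.values[row, col] == pytest.approx(0.5, abs=1e-9)

    def test_values_stay_within_input_range(self):
        rng = np.random.default_rng(6)
        s = samples_on_meridian(-7.0, 42.0, rng.uniform(0, 20_000, 10))
        vals = rng.uniform(0.0, 0.02, 10)
        vals[3] = np.nan  # missing values are excluded
        grid = idw_interpolate(s.lon, s.lat, vals, grid_cell_m=2000.0)
        valid = vals[np.isfinite(vals)]
        assert np.nanmin(grid.values) >= valid.min() - 1e-12
        assert np.nanmax(grid.values) <= valid.max() + 1e-12

    def test_all_missing_rejected(self):
        with pytest.raises(ArgumentError):
            idw_interpolate(np.array([0.0]), np.array([0.0]), np.array([np.nan]))
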