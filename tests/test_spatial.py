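"""Tests of the neighbour-coupling estimator, randomization test and
distance-tier profile."""

import numpy as np
import pandas as pd
import pytest

import noisetissue as nt
from noisetissue.errors import ParameterError

from conftest import make_normalized_table


def _coupled_pairs_table(n_pairs=50, intrinsic_sd=0.0, seed=0, anti=False):
    """Pairs of adjacent cells sharing an extrinsic factor; pairs far apart.

    With no intrinsic noise each cell's two channels are identical and so
    are the two cells of a pair -- stochastically identical neighbours.
    With ``anti``, the partner gets the reciprocal factor instead.
    """
    rng = np.random.default_rng(seed)
    e = rng.lognormal(0, 0.5, n_pairs)
    partner = 1.0 / e if anti else e
    c = np.empty(2 * n_pairs)
    y = np.empty(2 * n_pairs)
    x = np.empty(2 * n_pairs)
    yy = np.empty(2 * n_pairs)
    c[0::2] = e
    c[1::2] = partner
    y[0::2] = e
    y[1::2] = partner
    x[0::2] = 100.0 * np.arange(n_pairs)
    x[1::2] = 100.0 * np.arange(n_pairs) + 1.0
    yy[:] = 0.0
    if intrinsic_sd > 0:
        c *= rng.lognormal(0, intrinsic_sd, 2 * n_pairs)
        y *= rng.lognormal(0, intrinsic_sd, 2 * n_pairs)
    return make_normalized_table(c, y, x=x, yy=yy)


class TestKNearestNeighbours:
    def test_collinear_points(self):
        nn, dist = nt.k_nearest_neighbours([(0, 0), (1, 0), (3, 0)], 1)
        assert nn[:, 0].tolist() == [1, 0, 1]
        assert dist[:, 0].tolist() == [1.0, 1.0, 2.0]

    def test_k_equals_n_minus_one_returns_everyone_sorted(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 10, (8, 2))
        nn, dist = nt.k_nearest_neighbours(pos, 7)
        for i in range(8):
            assert sorted(nn[i]) == sorted(set(range(8)) - {i})
            assert (np.diff(dist[i]) >= 0).all()

    def test_matches_brute_force_all_pairs_sort(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 50, (100, 2))
        k = 10
        nn, _ = nt.k_nearest_neighbours(pos, k)
        for i in range(100):
            d = np.hypot(*(pos - pos[i]).T)
            d[i] = np.inf
            expect = sorted(range(100), key=lambda j: (d[j], j))[:k]
            assert nn[i].tolist() == expect

    def test_deterministic_tie_order_by_index(self):
        # four corners of a square: both side-neighbours tie; lower index wins
        pos = [(0, 0), (1, 0), (0, 1), (1, 1)]
        nn, _ = nt.k_nearest_neighbours(pos, 2)
        assert nn[0].tolist() == [1, 2]
        assert nn[3].tolist() == [1, 2]

    def test_k_too_large_rejected(self):
        with pytest.raises(ParameterError):
            nt.k_nearest_neighbours([(0, 0), (1, 1)], 2)


class TestNeighbourCorrelation:
    def test_stochastically_identical_neighbours_give_r_one(self):
        table = _coupled_pairs_table(intrinsic_sd=0.0)
        assert nt.neighbour_correlation(table) == pytest.approx(1.0)

    def test_normalization_undoes_intrinsic_attenuation(self):
        # the plain Pearson correlation of cell vs neighbour values is
        # attenuated by intrinsic noise; the covariance-normalized estimator
        # stays centred on 1 for fully shared extrinsic factors
        table = _coupled_pairs_table(500, intrinsic_sd=0.4, seed=3)
        wide = nt.cell_matrix(table)
        nn, _ = nt.k_nearest_neighbours(wide[["x_um", "y_um"]].to_numpy(), 1)
        c = wide["CFP"].to_numpy()
        y = wide["YFP"].to_numpy()
        pearson = np.corrcoef(c, y[nn[:, 0]])[0, 1]
        r = nt.neighbour_correlation(table)
        assert pearson < 0.9
        assert abs(r - 1.0) < 0.2
        assert r > pearson

    def test_uncoupled_tissue_gives_near_zero_r(self):
        table, _ = nt.generate_tissue(nt.TissueGenConfig(n_cells=500, coupling=0.0, seed=5))
        norm = nt.normalize_table(nt.average_duplicates(table))
        assert abs(nt.neighbour_correlation(norm)) < 0.15  # ~3 x null SD at n=500

    def test_channel_swap_symmetry(self):
        table, _ = nt.generate_tissue(nt.TissueGenConfig(
            n_cells=300, coupling=0.3, corr_length_um=40.0, seed=6))
        norm = nt.normalize_table(nt.average_duplicates(table))
        r = nt.neighbour_correlation(norm)
        cfg = nt.SpatialConfig(channels=("YFP", "CFP"))
        assert nt.neighbour_correlation(norm, cfg) == pytest.approx(r)

    def test_cell_relabelling_leaves_r_unchanged(self):
        table, _ = nt.generate_tissue(nt.TissueGenConfig(n_cells=200, coupling=0.3,
                                                         corr_length_um=40.0, seed=7))
        norm = nt.normalize_table(nt.average_duplicates(table))
        r = nt.neighbour_correlation(norm)
        relabelled = nt.NucleusTable(
            norm.data.assign(cell_id=lambda d: "x_" + d["cell_id"]), state=norm.state)
        assert nt.neighbour_correlation(relabelled) == pytest.approx(r)

    def test_recovers_generator_coupling_within_bootstrap_ci(self):
        table, _ = nt.generate_tissue(nt.TissueGenConfig(
            n_cells=2000, coupling=0.34, corr_length_um=40.0, seed=8))
        norm = nt.normalize_table(nt.average_duplicates(table))
        r, lo, hi = nt.neighbour_correlation_ci(norm, n_boot=500, seed=1)
        assert lo <= 0.34 <= hi

    def test_multi_image_table_rejected(self):
        t1, _ = nt.generate_tissue(nt.TissueGenConfig(n_cells=50, seed=1, image_id="a"))
        t2, _ = nt.generate_tissue(nt.TissueGenConfig(n_cells=50, seed=2, image_id="b"))
        both = nt.NucleusTable(pd.concat([t1.data, t2.data], ignore_index=True))
        with pytest.raises(ParameterError):
            nt.neighbour_correlation(nt.normalize_table(both))


class TestRandomizationTest:
    def test_strong_coupling_hits_the_permutation_floor(self):
        table = _coupled_pairs_table(100, intrinsic_sd=0.1, seed=9)
        cfg = nt.SpatialConfig(n_permutations=100, seed=0)
        assert nt.randomization_test(table, cfg) == pytest.approx(1 / 101)

    def test_anticoupled_data_gives_p_one(self):
        # observed r far below every permuted value -> one-sided p = 1
        table = _coupled_pairs_table(100, intrinsic_sd=0.1, seed=10, anti=True)
        cfg = nt.SpatialConfig(n_permutations=100, seed=0)
        assert nt.randomization_test(table, cfg) == 1.0

    def test_null_p_not_extreme_on_uncoupled_tissue(self):
        table, _ = nt.generate_tissue(nt.TissueGenConfig(n_cells=300, coupling=0.0, seed=11))
        norm = nt.normalize_table(nt.average_duplicates(table))
        p = nt.randomization_test(norm, nt.SpatialConfig(n_permutations=200, seed=1))
        assert 0.005 < p <= 1.0


class TestTierCorrelation:
    def test_tier_assignment_and_counts_on_handmade_line(self):
        # cells at x = 0, 10, 20, 30, 45: nn distances (10,10,10,10,15),
        # ring width 11; with k=2 the tier of each neighbour is ceil(d/11)
        x = np.array([0.0, 10.0, 20.0, 30.0, 45.0])
        rng = np.random.default_rng(12)
        e = rng.lognormal(0, 0.5, 5)
        table = make_normalized_table(e, e, x=x, yy=np.zeros(5))
        cfg = nt.SpatialConfig(k_neighbours=2, n_tiers=3, n_permutations=100)
        tiers = nt.tier_correlation(table, cfg)
        # hand count: d/11 -> tier: 10->1 (x6), 15->2 (x2), 20->2 (x2), 25->3 (x1... )
        assert [t.n_pairs for t in tiers] == [6, 3, 1]

    def test_distance_decaying_coupling_gives_decreasing_tier_means(self):
        # short correlation length for a steep profile; k large enough that
        # the fifth ring is fully sampled rather than corner-clipped
        table, _ = nt.generate_tissue(nt.TissueGenConfig(
            n_cells=2000, coupling=0.4, corr_length_um=25.0, seed=13))
        norm = nt.normalize_table(nt.average_duplicates(table))
        tiers = nt.tier_correlation(norm, nt.SpatialConfig(k_neighbours=85))
        means = [t.mean for t in tiers]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_uncoupled_tissue_tier_means_near_zero(self):
        table, _ = nt.generate_tissue(nt.TissueGenConfig(n_cells=1000, coupling=0.0, seed=14))
        norm = nt.normalize_table(nt.average_duplicates(table))
        tiers = nt.tier_correlation(norm, nt.SpatialConfig())
        for t in tiers:
            assert abs(t.mean) < 3 * t.sd / np.sqrt(t.n_pairs) + 0.02

    def test_tier_one_consistent_with_nearest_neighbour_r(self):
        table, _ = nt.generate_tissue(nt.TissueGenConfig(
            n_cells=1500, coupling=0.3, corr_length_um=40.0, seed=15))
        norm = nt.normalize_table(nt.average_duplicates(table))
        r = nt.neighbour_correlation(norm)
        t1 = nt.tier_correlation(norm, nt.SpatialConfig())[0]
        assert abs(t1.mean - r) < 3 * t1.sd / np.sqrt(t1.n_pairs) + 0.05


class TestAnalyzeSpatial:
    def test_full_analysis_consistency(self):
        table, _ = nt.generate_tissue(nt.TissueGenConfig(
            n_cells=400, coupling=0.34, corr_length_um=40.0, seed=16))
        norm = nt.normalize_table(nt.average_duplicates(table))
        cfg = nt.SpatialConfig(n_permutations=300, seed=2)
        res = nt.analyze_spatial(norm, cfg)
        assert res.r == pytest.approx(nt.neighbour_correlation(norm, cfg))
        assert res.n_cells == 400
        assert 0 < res.p <= 1
        assert len(res.tier_profile) == 5
        assert 15.0 < res.mean_nn_distance < 25.0
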