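"""B-spline MI estimator, pooled permutation null and block schedule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mignet.mi import (
    all_pairs_mi,
    block_schedule,
    build_null,
    build_spline_basis,
    mutual_information,
    pairwise_mi,
    rank_transform,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def cox_de_boor(z, i, k, t):
    """Direct Cox–de Boor recursion for basis function i of order k."""
    if k == 1:
        # half-open bins; the domain's right endpoint belongs to the last
        # nonempty interval
        if t[i] <= z < t[i + 1]:
            return 1.0
        if z == t[-1] and t[i] < t[i + 1] == t[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if t[i + k - 1] > t[i]:
        left = (z - t[i]) / (t[i + k - 1] - t[i]) * cox_de_boor(z, i, k - 1, t)
    right = 0.0
    if t[i + k] > t[i + 1]:
        right = (t[i + k] - z) / (t[i + k] - t[i + 1]) * cox_de_boor(z, i + 1, k - 1, t)
    return left + right


def hard_bin_mi(x, y, bins):
    """Exact discrete MI of the hard-binned contingency table (nats)."""
    m = len(x)
    def bin_of(r):
        z = (r - 1) / (m - 1) * bins
        return min(int(np.floor(z)), bins - 1)
    counts = np.zeros((bins, bins))
    for xi, yi in zip(x, y):
        counts[bin_of(xi), bin_of(yi)] += 1
    p = counts / m
    px, py = p.sum(axis=1), p.sum(axis=0)
    mi = 0.0
    for a in range(bins):
        for b in range(bins):
            if p[a, b] > 0:
                mi += p[a, b] * np.log(p[a, b] / (px[a] * py[b]))
    return mi


# ---------------------------------------------------------------------------
# rank transform
# ---------------------------------------------------------------------------

class TestRankTransform:
    def test_ascending_ranks(self):
        assert rank_transform([0.3, 1.2, 0.7]).tolist() == [1, 3, 2]

    def test_sorted_input_is_identity(self):
        m = 9
        assert rank_transform(np.arange(m)).tolist() == list(range(1, m + 1))

    def test_ties_stable_by_position_and_idempotent_rerun(self):
        v = [2.0, 1.0, 2.0, 0.5]
        first = rank_transform(v)
        assert first.tolist() == [3, 2, 4, 1]   # first 2.0 ranked before second
        assert np.array_equal(first, rank_transform(v))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False),
                    min_size=2, max_size=40))
    def test_output_is_permutation(self, values):
        r = rank_transform(values)
        assert sorted(r.tolist()) == list(range(1, len(values) + 1))


# ---------------------------------------------------------------------------
# spline basis
# ---------------------------------------------------------------------------

class TestSplineBasis:
    def test_order_one_is_hard_binning(self):
        basis = build_spline_basis(m=20, bins=5, order=1)
        assert np.array_equal(np.sort(basis.weights, axis=1)[:, -1],
                              np.ones(20))
        assert np.allclose(basis.weights.sum(axis=1), 1.0)

    @pytest.mark.parametrize("m,bins,order", [(10, 5, 2), (50, 10, 3),
                                              (100, 10, 4), (12, 12, 3)])
    def test_partition_of_unity_and_support(self, m, bins, order):
        basis = build_spline_basis(m, bins, order)
        assert np.abs(basis.weights.sum(axis=1) - 1.0).max() < 1e-12
        for row in basis.weights:
            nz = np.flatnonzero(row)
            assert nz.size <= order
            assert np.array_equal(nz, np.arange(nz[0], nz[0] + nz.size))

    def test_matches_cox_de_boor_recursion(self):
        m, bins, order = 100, 10, 3
        basis = build_spline_basis(m, bins, order)
        t = np.concatenate([np.zeros(order),
                            np.arange(1.0, bins - order + 1),
                            np.full(order, bins - order + 1.0)])
        z = np.arange(m) / (m - 1) * (bins - order + 1)
        expected = np.array(
            [[cox_de_boor(zr, i, order, t) for i in range(bins)] for zr in z]
        )
        assert np.abs(basis.weights - expected).max() < 1e-12

    def test_bins_below_order_rejected(self):
        with pytest.raises(ValueError, match="bins >= order"):
            build_spline_basis(m=20, bins=2, order=3)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_self_mi_is_marginal_entropy_under_hard_binning(self, rng):
        # the joint of (x, x) collapses to a diagonal only when each
        # observation sits in exactly one bin, i.e. with an order-1 basis
        basis = build_spline_basis(30, bins=6, order=1)
        x = rank_transform(rng.standard_normal(30))
        assert np.isclose(mutual_information(x, x, basis),
                          basis.marginal_entropy(), atol=1e-12)

    def test_self_mi_is_maximal_over_partners(self, rng):
        basis = build_spline_basis(30, bins=6, order=3)
        x = rank_transform(rng.standard_normal(30))
        self_mi = mutual_information(x, x, basis)
        for _ in range(10):
            y = rank_transform(rng.standard_normal(30))
            assert mutual_information(x, y, basis) <= self_mi + 1e-12

    def test_order_one_equals_contingency_table_mi(self):
        basis = build_spline_basis(4, bins=2, order=1)
        x = np.array([1, 2, 3, 4])
        y = np.array([4, 3, 2, 1])
        assert np.isclose(mutual_information(x, y, basis),
                          hard_bin_mi(x, y, 2), atol=1e-12)

    def test_order_one_equals_contingency_mi_exhaustively(self, rng):
        # random spot checks over small m and bins
        for m in (6, 9, 12):
            for bins in (2, 3, 4):
                basis = build_spline_basis(m, bins=bins, order=1)
                for _ in range(20):
                    x = rank_transform(rng.random(m))
                    y = rank_transform(rng.random(m))
                    assert np.isclose(
                        mutual_information(x, y, basis),
                        hard_bin_mi(x, y, bins), atol=1e-10,
                    )

    def test_symmetry(self, rng):
        basis = build_spline_basis(25, bins=8, order=3)
        for _ in range(20):
            x = rank_transform(rng.standard_normal(25))
            y = rank_transform(rng.standard_normal(25))
            assert abs(mutual_information(x, y, basis)
                       - mutual_information(y, x, basis)) < 1e-12

    def test_invariant_under_monotone_transform(self, rng):
        basis = build_spline_basis(40, bins=8, order=3)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        base = mutual_information(rank_transform(x), rank_transform(y), basis)
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            assert mutual_information(
                rank_transform(f(x)), rank_transform(y), basis
            ) == base

    def test_shared_marginal_entropy_across_genes(self, rng):
        basis = build_spline_basis(30, bins=6, order=3)
        h = basis.marginal_entropy()
        for _ in range(10):
            ranks = rank_transform(rng.standard_normal(30))
            w = basis.weights[ranks - 1]
            p = w.mean(axis=0)
            assert np.isclose(-(p[p > 0] * np.log(p[p > 0])).sum(), h,
                              atol=1e-12)

    def test_length_mismatch_rejected(self):
        basis = build_spline_basis(10, bins=5, order=2)
        with pytest.raises(ValueError, match="length"):
            mutual_information(np.arange(1, 10), np.arange(1, 11), basis)


# ---------------------------------------------------------------------------
# pooled null
# ---------------------------------------------------------------------------

class TestNullModel:
    def test_resolution_guard(self):
        with pytest.raises(ValueError, match="resolvable"):
            build_null(m=20, P_perm=100, epsilon=1e-4, bins=5, order=2)

    def test_threshold_is_max_when_epsilon_one_over_p(self):
        null = build_null(m=30, P_perm=50, epsilon=1.0 / 50, seed=3,
                          bins=5, order=2)
        assert null.threshold == null.samples[-1]

    def test_direct_count_semantics(self):
        from mignet.mi import NullModel
        null = NullModel(samples=np.array([0.1, 0.2, 0.3]),
                         epsilon=1.0 / 3, threshold=0.3)
        assert bool(null.is_significant(0.25))       # beats 2/3 of samples
        assert not bool(null.is_significant(0.15))   # beats only 1/3

    def test_reproducible_under_seed(self):
        a = build_null(m=25, P_perm=300, epsilon=0.01, seed=11, bins=5, order=2)
        b = build_null(m=25, P_perm=300, epsilon=0.01, seed=11, bins=5, order=2)
        assert np.array_equal(a.samples, b.samples)
        assert a.threshold == b.threshold

    def test_false_positive_rate_matches_epsilon(self, rng):
        # i.i.d. noise profiles: the edge-call rate estimates epsilon
        eps, m, n, reps = 0.05, 100, 15, 4
        basis = build_spline_basis(m, bins=10, order=3)
        null = build_null(m, P_perm=4000, basis=basis, epsilon=eps, seed=9)
        calls = trials = 0
        for _ in range(reps):
            mat = make_matrix(rng.standard_normal((n, m)))
            mi = pairwise_mi(mat, basis=basis)
            iu = np.triu_indices(n, 1)
            calls += int(null.is_significant(mi[iu]).sum())
            trials += iu[0].size
        rate = calls / trials
        se = np.sqrt(eps * (1 - eps) / trials)
        assert abs(rate - eps) < 3 * se


# ---------------------------------------------------------------------------
# block schedule
# ---------------------------------------------------------------------------

class TestBlockSchedule:
    def test_single_processor(self):
        s = block_schedule(1)
        assert [(a.block_row, a.block_col) for a in s.assignments] == [(0, 0)]

    def test_three_processors_cover_all_pairs_once(self):
        s = block_schedule(3)
        stages = {a.stage for a in s.assignments}
        assert stages == {0, 1}
        assert len(s.assignments) == 6
        assert s.covered_pairs() == {
            (a, b): 1.0 for a in range(3) for b in range(a, 3)
        }

    def test_even_p_final_stage_is_halved_duplicates(self):
        s = block_schedule(4)
        last = [a for a in s.assignments if a.stage == 2]
        assert len(last) == 4 and all(a.half for a in last)
        pairs = {tuple(sorted((a.block_row, a.block_col))) for a in last}
        assert len(pairs) == 2

    @pytest.mark.parametrize("p", range(1, 17))
    def test_coverage_invariant(self, p):
        cover = block_schedule(p).covered_pairs()
        expected = {(a, b) for a in range(p) for b in range(a, p)}
        assert set(cover) == expected
        assert all(np.isclose(v, 1.0) for v in cover.values())

    def test_column_follows_circular_shift(self):
        for a in block_schedule(5).assignments:
            assert a.block_col == (a.rank + a.stage) % 5


# ---------------------------------------------------------------------------
# all-pairs driver
# ---------------------------------------------------------------------------

class TestAllPairsMI:
    def test_identical_profiles_fully_connected_at_max_weight(self, rng):
        profile = rng.standard_normal(40)
        mat = make_matrix(np.vstack([profile, profile, profile]))
        net = all_pairs_mi(mat, bins=5, order=2, epsilon=0.1,
                           P_perm=200, seed=0)
        assert net.number_of_edges() == 3
        weights = {d["weight"] for _, _, d in net.edges(data=True)}
        assert len(weights) == 1

    def test_worker_count_does_not_change_result(self, rng):
        mat = make_matrix(rng.standard_normal((9, 30)))
        nets = [
            all_pairs_mi(mat, bins=5, order=2, epsilon=0.2,
                         P_perm=100, seed=4, workers=w)
            for w in (1, 4)
        ]
        assert set(nets[0].edges()) == set(nets[1].edges())
        for u, v in nets[0].edges():
            assert nets[0][u][v]["weight"] == nets[1][u][v]["weight"]

    def test_noise_edge_rate_tracks_epsilon(self, rng):
        eps = 0.05
        mat = make_matrix(rng.standard_normal((20, 120)))
        net = all_pairs_mi(mat, bins=10, order=3, epsilon=eps,
                           P_perm=2000, seed=8)
        n_pairs = 20 * 19 // 2
        se = np.sqrt(eps * (1 - eps) * n_pairs)
        assert abs(net.number_of_edges() - eps * n_pairs) < 3 * se + 1

    def test_parameters_recorded_on_graph(self, rng):
        mat = make_matrix(rng.standard_normal((4, 25)))
        net = all_pairs_mi(mat, bins=5, order=2, epsilon=0.1,
                           P_perm=50, seed=2)
        assert net.graph["bins"] == 5 and net.graph["P_perm"] == 50
        assert net.graph["seed"] == 2 and "threshold" in net.graph

    def test_single_gene_rejected(self):
        mat = make_matrix(np.zeros((1, 20)) + np.arange(20))
        with pytest.raises(ValueError, match="2 genes"):
            all_pairs_mi(mat, bins=5, order=2, epsilon=0.5, P_perm=10)
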