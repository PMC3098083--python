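"""Chaotic map clustering: couplings, dynamics, MI, hierarchy, selection."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from cmclust.cmc import (
    LN2,
    BitSequences,
    CMCParams,
    cluster_entropy,
    cmc_cluster,
    compute_couplings,
    evolve_maps,
    mutual_information,
    partition_at,
    select_plateau,
    sweep_hierarchy,
)
from cmclust.matrices import LabeledSquareMatrix
from cmclust.synthetic import PlantedPartitionSpec, planted_distances

from conftest import random_distance


def mi_matrix(values, labels=None):
    values = np.asarray(values, float)
    n = len(values)
    labels = labels or tuple(f"m{i}" for i in range(n))
    from cmclust.cmc import MIMatrix

    return MIMatrix(tuple(labels), values, np.diag(values).copy())


class TestComputeCouplings:
    def test_zero_distance_pair_has_unit_coupling(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        D = LabeledSquareMatrix(("a", "b", "c"), d, "distance")
        coup = compute_couplings(D, K=1)
        assert coup.J[0, 1] == 1.0

    def test_exponent_at_scale_times_sqrt2(self):
        # with both off-diagonal distances equal, a equals that distance,
        # so a pair at a*sqrt(2) has J = exp(-1)
        base = 0.5
        d = base * math.sqrt(2.0)
        v = np.array([[0.0, d, base], [d, 0.0, base], [base, base, 0.0]])
        # K=2: each row's two neighbours -> a = mean of all off-diag entries
        D = LabeledSquareMatrix(("a", "b", "c"), v, "distance")
        coup = compute_couplings(D, K=2)
        a_expected = (2 * d + 4 * base) / 6.0
        assert coup.a == pytest.approx(a_expected)
        assert coup.J[0, 1] == pytest.approx(math.exp(-d * d / (2 * a_expected ** 2)))

    def test_dense_limit_matches_brute_force(self, rng):
        D = random_distance(rng, 4)
        coup = compute_couplings(D, K=3)
        # K = N-1: no sparsification; a is the grand mean off-diag distance
        off = ~np.eye(4, dtype=bool)
        a = D.values[off].mean()
        expected = np.exp(-D.values ** 2 / (2 * a * a))
        np.fill_diagonal(expected, 0.0)
        assert coup.a == pytest.approx(a)
        np.testing.assert_allclose(coup.J, expected, atol=1e-12)
        np.testing.assert_allclose(coup.C, expected.sum(axis=1))

    def test_rejects_zero_scale_and_bad_k(self):
        D = LabeledSquareMatrix(("a", "b"), np.zeros((2, 2)), "distance")
        with pytest.raises(ValueError, match="zero"):
            compute_couplings(D, K=1)
        with pytest.raises(ValueError, match="K must lie"):
            compute_couplings(D, K=2)

    def test_symmetrized_union_graph_when_sparsified(self, rng):
        D = random_distance(rng, 6)
        coup = compute_couplings(D, K=2, sparsify=True)
        np.testing.assert_allclose(coup.J, coup.J.T)
        assert (np.diag(coup.J) == 0).all()
        assert ((coup.J >= 0) & (coup.J <= 1)).all()
        # a pair is coupled iff either item lists the other among its 2 NN
        masked = D.values + np.where(np.eye(6, dtype=bool), np.inf, 0.0)
        order = np.argsort(masked, axis=1)[:, :2]
        expected = np.zeros((6, 6), dtype=bool)
        for i in range(6):
            expected[i, order[i]] = True
        expected |= expected.T
        np.testing.assert_array_equal(coup.J > 0, expected)

    def test_dense_default_couples_every_pair(self, rng):
        D = random_distance(rng, 6)
        coup = compute_couplings(D, K=2)
        off = ~np.eye(6, dtype=bool)
        assert (coup.J[off] > 0).all()


class TestEvolveMaps:
    def test_isolated_item_follows_bare_logistic_orbit(self):
        # one coupled pair plus one isolated item (no coupling edges to it)
        from cmclust.cmc import CouplingMatrix

        J = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        coup = CouplingMatrix(("a", "b", "c"), J, a=1.0)
        params = CMCParams(K=1, n_iter=50, transient=0, seed=9)
        _, states = evolve_maps(coup, params, return_states=True)
        x0 = np.random.default_rng(9).uniform(-1, 1, 3)[2]
        expected = []
        x = x0
        for _ in range(50):
            x = 1.0 - 2.0 * x * x
            expected.append(x)
        np.testing.assert_allclose(states[2], expected, rtol=1e-12)

    def test_states_stay_in_unit_interval(self, rng):
        D = random_distance(rng, 10)
        coup = compute_couplings(D, K=3)
        _, states = evolve_maps(
            coup, CMCParams(K=3, n_iter=2000, transient=0, seed=4), return_states=True
        )
        assert states.min() >= -1.0 and states.max() <= 1.0

    def test_tight_family_synchronizes(self):
        # six items at near-zero mutual distance: maps synchronize and the
        # recorded bit sequences coincide across the family
        n = 6
        d = np.full((n, n), 0.01)
        np.fill_diagonal(d, 0.0)
        D = LabeledSquareMatrix(tuple("abcdef"), d, "distance")
        coup = compute_couplings(D, K=n - 1)
        bits = evolve_maps(coup, CMCParams(K=n - 1, n_iter=3000, transient=500, seed=2))
        for i in range(1, n):
            np.testing.assert_array_equal(bits.bits[i], bits.bits[0])

    def test_deterministic_given_seed(self, rng):
        D = random_distance(rng, 8)
        coup = compute_couplings(D, K=3)
        p = CMCParams(K=3, n_iter=500, transient=100, seed=11)
        b1 = evolve_maps(coup, p)
        b2 = evolve_maps(coup, p)
        np.testing.assert_array_equal(b1.bits, b2.bits)


class TestMutualInformation:
    def test_identical_balanced_sequences_give_ln2(self):
        bits = np.tile(np.array([[0, 1, 1, 0, 1, 0, 0, 1]], dtype=np.uint8), (2, 1))
        mi = mutual_information(BitSequences(("a", "b"), bits))
        assert mi.I[0, 1] == pytest.approx(LN2, abs=1e-12)

    def test_complementary_balanced_sequences_give_ln2(self):
        s = np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=np.uint8)
        bits = np.stack([s, 1 - s])
        mi = mutual_information(BitSequences(("a", "b"), bits))
        assert mi.I[0, 1] == pytest.approx(LN2, abs=1e-12)

    def test_independent_sequences_give_near_zero(self, rng):
        bits = (rng.random((2, 10000)) < 0.5).astype(np.uint8)
        mi = mutual_information(BitSequences(("a", "b"), bits))
        assert abs(mi.I[0, 1]) < 5e-3

    def test_matches_brute_force_counting(self, rng):
        bits = (rng.random((3, 200)) < 0.4).astype(np.uint8)
        mi = mutual_information(BitSequences(("a", "b", "c"), bits))
        T = bits.shape[1]
        for i, j in itertools.combinations(range(3), 2):
            joint = np.zeros((2, 2))
            for t in range(T):
                joint[bits[i, t], bits[j, t]] += 1
            joint /= T
            pi, pj = joint.sum(axis=1), joint.sum(axis=0)

            def h(p):
                p = p[p > 0]
                return -(p * np.log(p)).sum()

            expected = h(pi) + h(pj) - h(joint.ravel())
            assert mi.I[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounds_symmetry_and_self_information(self, rng):
        bits = (rng.random((5, 300)) < 0.5).astype(np.uint8)
        mi = mutual_information(BitSequences(tuple("abcde"), bits))
        assert (mi.I >= 0).all() and (mi.I <= LN2 + 1e-12).all()
        np.testing.assert_allclose(mi.I, mi.I.T)
        np.testing.assert_allclose(np.diag(mi.I), mi.H, atol=1e-12)


class TestPartitionAt:
    def test_theta_ln2_gives_all_singletons(self, rng):
        mi = mi_matrix(np.full((4, 4), LN2))
        assert len(partition_at(mi, LN2)) == 4

    def test_theta_below_min_gives_one_cluster(self, rng):
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, LN2)
        assert len(partition_at(mi_matrix(v), 0.1)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx_components(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, LN2, (6, 6))
        v = (v + v.T) / 2
        mi = mi_matrix(v)
        theta = float(rng.uniform(0, LN2))
        got = {frozenset(c) for c in partition_at(mi, theta)}
        g = nx.Graph()
        g.add_nodes_from(mi.labels)
        for i in range(6):
            for j in range(i + 1, 6):
                if v[i, j] > theta:
                    g.add_edge(mi.labels[i], mi.labels[j])
        expected = {frozenset(c) for c in nx.connected_components(g)}
        assert got == expected


class TestClusterEntropy:
    def test_closed_forms(self):
        one = [frozenset(f"x{i}" for i in range(10))]
        assert cluster_entropy(one, 10) == 0.0
        halves = [frozenset(f"a{i}" for i in range(5)), frozenset(f"b{i}" for i in range(5))]
        assert cluster_entropy(halves, 10) == pytest.approx(LN2)
        singles = [frozenset([f"s{i}"]) for i in range(8)]
        assert cluster_entropy(singles, 8) == pytest.approx(math.log(8))

    def test_rejects_empty_or_mismatched(self):
        with pytest.raises(ValueError):
            cluster_entropy([], 3)
        with pytest.raises(ValueError):
            cluster_entropy([frozenset(["a"])], 3)


class TestSweepAndPlateau:
    def test_all_zero_mi_gives_singletons_everywhere(self):
        mi = mi_matrix(np.zeros((5, 5)))
        hierarchy = sweep_hierarchy(mi, 0.01)
        for theta, part, entropy in hierarchy:
            assert len(part) == 5
            assert entropy == pytest.approx(math.log(5))

    def test_all_ln2_mi_gives_one_cluster_everywhere(self):
        v = np.full((5, 5), LN2)
        hierarchy = sweep_hierarchy(mi_matrix(v), 0.01)
        # every swept bin edge is strictly below ln 2, so the graph is complete
        for theta, part, entropy in hierarchy:
            assert len(part) == 1
            assert entropy == 0.0

    def test_partitions_refine_and_entropy_non_decreasing(self, rng):
        v = rng.uniform(0, LN2, (8, 8))
        v = (v + v.T) / 2
        hierarchy = sweep_hierarchy(mi_matrix(v), 0.05)
        entropies = [s for _, _, s in hierarchy]
        assert all(a <= b + 1e-12 for a, b in zip(entropies, entropies[1:]))
        for (_, coarse, _), (_, fine, _) in zip(hierarchy, hierarchy[1:]):
            for cluster in fine:
                assert any(cluster <= big for big in coarse)

    def test_first_longest_run_is_selected(self):
        # craft MI whose sweep produces runs of lengths 2, then 5, then the rest
        parts = []
        # use select_plateau directly on a synthetic hierarchy
        p1 = [frozenset(["a", "b", "c"])]
        p2 = [frozenset(["a", "b"]), frozenset(["c"])]
        p3 = [frozenset(["a"]), frozenset(["b"]), frozenset(["c"])]
        hierarchy = (
            [(0.00 + 0.01 * k, p1, 0.0) for k in range(2)]
            + [(0.02 + 0.01 * k, p2, 0.6) for k in range(5)]
            + [(0.07 + 0.01 * k, p3, 1.1) for k in range(5)]
        )
        theta, part = select_plateau(hierarchy)
        assert part == p2
        assert theta == pytest.approx((0.02 + 0.06) / 2)

    def test_single_level_hierarchy(self):
        p = [frozenset(["a"]), frozenset(["b"])]
        theta, part = select_plateau([(0.3, p, LN2)])
        assert (theta, part) == (0.3, p)

    def test_planted_two_cluster_mi_selects_planted_partition(self):
        labels = tuple(f"m{i}" for i in range(8))
        v = np.zeros((8, 8))
        v[:4, :4] = LN2
        v[4:, 4:] = LN2
        theta, part = select_plateau(sweep_hierarchy(mi_matrix(v, labels), 0.01))
        assert {frozenset(c) for c in part} == {
            frozenset(labels[:4]),
            frozenset(labels[4:]),
        }


class TestCMCCluster:
    def test_recovers_planted_two_by_ten_partition(self):
        spec = PlantedPartitionSpec(sizes=(10, 10), seed=21)
        D, truth = planted_distances(spec)
        res = cmc_cluster(D, CMCParams(K=5, seed=1))
        pred = [res.assignments()[l] for l in D.labels]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_deterministic_end_to_end(self):
        spec = PlantedPartitionSpec(sizes=(6, 6), seed=3)
        D, _ = planted_distances(spec)
        p = CMCParams(K=4, n_iter=3000, transient=500, seed=7)
        r1, r2 = cmc_cluster(D, p), cmc_cluster(D, p)
        np.testing.assert_array_equal(r1.mi.I, r2.mi.I)
        assert r1.selected_theta == r2.selected_theta
        assert r1.selected_partition == r2.selected_partition

    def test_label_swap_permutes_partition(self):
        spec = PlantedPartitionSpec(sizes=(6, 6), seed=5)
        D, _ = planted_distances(spec)
        labels = list(D.labels)
        swapped = labels.copy()
        swapped[0], swapped[-1] = swapped[-1], swapped[0]
        # same matrix content, rows/cols reordered: clusters must carry the
        # relabelling and nothing else
        Dp = D.permuted(swapped)
        p = CMCParams(K=4, n_iter=3000, transient=500, seed=7)
        part_a = {frozenset(c) for c in cmc_cluster(D, p).selected_partition}
        part_b = {frozenset(c) for c in cmc_cluster(Dp, p).selected_partition}
        assert part_a == part_b

    def test_theta_override_bypasses_plateau(self):
        spec = PlantedPartitionSpec(sizes=(6, 6), seed=8)
        D, _ = planted_distances(spec)
        res = cmc_cluster(D, CMCParams(K=4, seed=1, theta_override=0.08,
                                       n_iter=3000, transient=500))
        assert res.selected_theta == 0.08
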