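import numpy as np
import pytest

import pharmconn as pc
from pharmconn.graph import (
    DMNGraph,
    Partition,
    build_dmn_graph,
    gamma_sweep,
    louvain_signed,
    nmi,
    signed_modularity,
    stability_analysis,
    subnetwork_tests,
)

from conftest import make_diff


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def set_partitions(n):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, max_label):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def exhaustive_best_q(weights, gamma=1.0):
    best_q, best_labels = -np.inf, None
    for labels in set_partitions(weights.shape[0]):
        q = signed_modularity(weights, labels, gamma)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    return best_q, best_labels


def newman_positive_modularity(weights, labels, gamma=1.0):
    """Independent direct-formula Newman modularity for nonnegative weights."""
    w = np.asarray(weights, dtype=float)
    s = w.sum(axis=1)
    v = w.sum()
    q = 0.0
    for i in range(w.shape[0]):
        for j in range(w.shape[0]):
            if labels[i] == labels[j]:
                q += w[i, j] - gamma * s[i] * s[j] / v
    return q / v


def two_cliques(k=3):
    w = np.zeros((2 * k, 2 * k))
    w[:k, :k] = 1.0
    w[k:, k:] = 1.0
    np.fill_diagonal(w, 0.0)
    return DMNGraph(nodes=np.arange(2 * k), weights=w)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


class TestBuildGraph:
    def test_identical_rows_full_similarity(self):
        t = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        g = build_dmn_graph(make_diff(t))
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_negated_rows_opposite(self):
        t = np.array([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        g = build_dmn_graph(make_diff(t))
        assert g.weights[0, 1] == pytest.approx(-1.0)

    def test_matches_definitional_cosine(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal((3, 4))
        g = build_dmn_graph(make_diff(t))
        for i in range(3):
            for j in range(i + 1, 3):
                expected = t[i] @ t[j] / (
                    np.linalg.norm(t[i]) * np.linalg.norm(t[j])
                )
                assert g.weights[i, j] == pytest.approx(expected, abs=1e-12)

    def test_pearson_option_matches_corrcoef(self):
        rng = np.random.default_rng(2)
        t = rng.standard_normal((4, 6))
        g = build_dmn_graph(make_diff(t), similarity="pearson")
        ref = np.corrcoef(t)
        np.fill_diagonal(ref, 0.0)
        assert np.allclose(g.weights, ref, atol=1e-12)

    def test_all_zero_profile_gets_zero_weight(self):
        t = np.array([[1.0, 2.0], [3.0, 1.0], [5.0, 2.0]])
        mask = np.array([[False, False], [True, True], [True, True]])
        g = build_dmn_graph(make_diff(t, mask=mask))
        assert np.all(g.weights[0] == 0.0)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="2 DMN nodes"):
            build_dmn_graph(make_diff(np.array([[1.0, 2.0]])))


# ---------------------------------------------------------------------------
# signed modularity
# ---------------------------------------------------------------------------


class TestSignedModularity:
    def test_two_cliques_true_partition(self):
        g = two_cliques()
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert signed_modularity(g, labels) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        g = two_cliques()
        assert signed_modularity(g, np.zeros(6, dtype=int)) == pytest.approx(0.0)

    def test_all_negative_complete_graph_singletons(self):
        # v- = 12, intra sums are only the i = j null terms: Q- = -4*9/144
        # = -0.25, and Q = -(v-/v)*Q- = +0.25 (singletons avoid all the
        # negative weight the null model expects inside communities)
        w = -np.ones((4, 4))
        np.fill_diagonal(w, 0.0)
        g = DMNGraph(nodes=np.arange(4), weights=w)
        assert signed_modularity(g, np.arange(4)) == pytest.approx(0.25)

    def test_reduces_to_newman_on_positive_weights(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            w = rng.uniform(0, 1, size=(n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            labels = rng.integers(0, 3, size=n)
            gamma = float(rng.uniform(0.5, 2.0))
            assert signed_modularity(w, labels, gamma) == pytest.approx(
                newman_positive_modularity(w, labels, gamma), abs=1e-12
            )


# ---------------------------------------------------------------------------
# Louvain optimisation
# ---------------------------------------------------------------------------


class TestLouvain:
    def test_two_cliques_recovered_any_seed(self):
        g = two_cliques()
        for seed in range(5):
            part = louvain_signed(g, seed=seed)
            assert part.n_communities == 2
            assert part.q_value == pytest.approx(0.5)
            assert len(set(part.labels[:3])) == 1
            assert len(set(part.labels[3:])) == 1

    def test_complete_positive_graph_single_community(self):
        w = np.ones((4, 4))
        np.fill_diagonal(w, 0.0)
        g = DMNGraph(nodes=np.arange(4), weights=w)
        part = louvain_signed(g, seed=0)
        assert part.n_communities == 1
        assert part.q_value == pytest.approx(0.0)
        best_q, _ = exhaustive_best_q(w)
        assert best_q == pytest.approx(0.0)

    def test_signed_planted_triples(self):
        w = np.full((6, 6), -1.0)
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        np.fill_diagonal(w, 0.0)
        g = DMNGraph(nodes=np.arange(6), weights=w)
        part = louvain_signed(g, seed=1)
        best_q, best_labels = exhaustive_best_q(w)
        assert part.q_value == pytest.approx(best_q)
        assert nmi(part.labels, best_labels) == pytest.approx(1.0)

    def test_matches_exhaustive_on_small_random_signed_graphs(self):
        rng = np.random.default_rng(17)
        failures = 0
        trials = 15
        for trial in range(trials):
            n = int(rng.integers(5, 8))
            w = rng.uniform(-1, 1, size=(n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            g = DMNGraph(nodes=np.arange(n), weights=w)
            part = louvain_signed(g, seed=trial)
            best_q, _ = exhaustive_best_q(w)
            if not np.isclose(part.q_value, best_q, atol=1e-9):
                failures += 1
        assert failures <= max(1, int(0.02 * trials) + 1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(-1, 1, size=(12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = DMNGraph(nodes=np.arange(12), weights=w)
        a = louvain_signed(g, seed=99)
        b = louvain_signed(g, seed=99)
        assert np.array_equal(a.labels, b.labels)
        assert a.q_value == b.q_value


# ---------------------------------------------------------------------------
# NMI
# ---------------------------------------------------------------------------


class TestNMI:
    def test_identical_partitions(self):
        assert nmi(np.array([0, 0, 1, 2]), np.array([5, 5, 7, 9])) == 1.0

    def test_independent_partitions(self):
        assert nmi(np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2])) == pytest.approx(0.0, abs=1e-12)

    def test_hand_contingency_value(self):
        # A=[1,1,2], B=[1,2,2]; contingency {(1,1):1, (1,2):1, (2,2):1}
        # I = (1/3)[ln(3/2) + ln(3/4) + ln(3/2)] = (1/3) ln(27/16)
        a, b = np.array([1, 1, 2]), np.array([1, 2, 2])
        i_ab = np.log(27 / 16) / 3
        h = -(1 / 3) * np.log(1 / 3) - (2 / 3) * np.log(2 / 3)
        assert nmi(a, b) == pytest.approx(2 * i_ab / (2 * h), abs=1e-12)
        assert nmi(a, b) == pytest.approx(0.2740175, abs=1e-6)

    def test_both_trivial_partitions(self):
        assert nmi(np.zeros(5, dtype=int), np.zeros(5, dtype=int)) == 1.0

    def test_symmetric_bounded_label_invariant(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(3, 20))
            a = rng.integers(0, 4, size=n)
            b = rng.integers(0, 4, size=n)
            v = nmi(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(nmi(b, a), abs=1e-12)
            perm = rng.permutation(10)
            assert nmi(perm[a], b) == pytest.approx(v, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import normalized_mutual_info_score

        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            a = rng.integers(0, 3, size=n)
            b = rng.integers(0, 3, size=n)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            ref = normalized_mutual_info_score(a, b, average_method="arithmetic")
            assert nmi(a, b) == pytest.approx(ref, abs=1e-9)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            nmi(np.array([0, 1]), np.array([0, 1, 2]))


# ---------------------------------------------------------------------------
# stability and resolution sweep
# ---------------------------------------------------------------------------


class TestStability:
    def test_unique_optimum_gives_constant_nmi(self):
        report = stability_analysis(two_cliques(), n_iterations=2, seed=0)
        assert report.min_pairwise_nmi == 1.0
        assert report.mean_pairwise_nmi == 1.0

    def test_noise_graph_is_unstable(self):
        # 30 nodes of i.i.d. noise: many near-degenerate optima, so repeated
        # seeded runs disagree (unlike the planted scenarios, where they
        # agree exactly)
        unstable = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = rng.uniform(-0.05, 0.05, size=(30, 30))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            g = DMNGraph(nodes=np.arange(30), weights=w)
            report = stability_analysis(g, n_iterations=5, seed=seed)
            if report.min_pairwise_nmi < 1.0:
                unstable += 1
        assert unstable > 10

    def test_consensus_is_highest_q(self):
        report = stability_analysis(two_cliques(), n_iterations=4, seed=3)
        assert report.consensus.q_value == pytest.approx(0.5)


class TestGammaSweep:
    def test_reference_gamma_self_agreement(self):
        sweep = gamma_sweep(two_cliques(), [1.0], seed=0)
        assert sweep[0][1] == 1.0

    def test_two_cliques_stable_across_moderate_gamma(self):
        sweep = gamma_sweep(two_cliques(), [0.5, 1.0, 1.5], seed=0)
        for gamma, value, k in sweep:
            assert k == 2
            assert value == 1.0

    def test_large_gamma_recorded_without_error(self):
        sweep = gamma_sweep(two_cliques(), [10.0], seed=0)
        assert sweep[0][2] >= 2

    def test_empty_gamma_list_rejected(self):
        with pytest.raises(ValueError):
            gamma_sweep(two_cliques(), [], seed=0)


# ---------------------------------------------------------------------------
# sub-network tests
# ---------------------------------------------------------------------------


class TestSubnetworkTests:
    def test_single_community_reduces_to_networkwise(self, toy_run):
        _, result = toy_run
        diff, parc = result.diff, result.parcellation
        part = Partition(
            nodes=diff.rows,
            labels=np.zeros(diff.rows.size, dtype=int),
            q_value=0.0,
            gamma=1.0,
        )
        sub = subnetwork_tests(diff, part, parc)
        whole = pc.networkwise_tests(diff, parc)
        assert len(sub) == len(whole)
        for a, b in zip(sub, whole):
            if a.testable:
                assert a.t == pytest.approx(b.t)
                assert a.df == b.df
                # only the Bonferroni family size differs (x n_communities)
                assert a.p_bonf == pytest.approx(min(1.0, b.p_uncorrected * 3))

    def test_planted_scenario_opposite_signs(self, toy_run):
        _, result = toy_run
        truth = result.truth
        labels = truth.dmn_labels
        by_label = {}
        for lab in range(result.partition.n_communities):
            members = result.partition.members(lab)
            planted = labels[members]
            by_label[lab] = int(np.bincount(planted).argmax())
        for r in result.subnetwork_results:
            planted_sub = by_label[r.subnetwork]
            for sub, target, delta in truth.effect_map:
                if sub == planted_sub and r.network == target and r.testable:
                    assert np.sign(r.t) == np.sign(delta)

    def test_symmetric_cell_null(self):
        diff = make_diff(np.array([[2.0, -2.0], [2.0, -2.0]]),
                         col_networks=("Aud", "Aud"))
        parc = pc.Parcellation(
            node_id=np.arange(4), label=tuple("abcd"),
            network=("DefaultMode", "DefaultMode", "Aud", "Aud"),
            dmn_name="DefaultMode",
        )
        part = Partition(nodes=diff.rows, labels=np.array([0, 1]),
                         q_value=0.0, gamma=1.0)
        res = subnetwork_tests(diff, part, parc)
        for r in res:
            if r.testable:
                assert r.t == pytest.approx(0.0)
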