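import numpy as np
import pytest
from scipy import stats as sps

import pharmconn as pc
from pharmconn import synth
from pharmconn.stats import (
    bh_fdr,
    extract_difference_matrix,
    networkwise_tests,
    overall_test,
    paired_edge_tests,
)

from conftest import make_diff


def _grids_from_diffs(diffs):
    """Build (S, 2, 2) placebo/drug stacks with the given per-subject
    differences planted on the off-diagonal edge."""
    diffs = np.asarray(diffs, dtype=float)
    s = diffs.size
    placebo = np.zeros((s, 2, 2))
    drug = np.zeros((s, 2, 2))
    drug[:, 0, 1] = drug[:, 1, 0] = diffs
    return placebo, drug


class TestPairedEdgeTests:
    def test_symmetric_differences_give_null(self):
        placebo, drug = _grids_from_diffs([1.0, -1.0, 1.0, -1.0])
        t, p, mean, df = paired_edge_tests(placebo, drug)
        assert t[0, 1] == pytest.approx(0.0)
        assert p[0, 1] == pytest.approx(1.0)
        assert df == 3

    def test_hand_closed_form(self):
        # d = [2, 4, 6]: mean 4, sd 2 -> t = 4 / (2 / sqrt(3)) = 2 sqrt(3)
        placebo, drug = _grids_from_diffs([2.0, 4.0, 6.0])
        t, p, mean, df = paired_edge_tests(placebo, drug)
        assert t[0, 1] == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert t[0, 1] == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        assert mean[0, 1] == pytest.approx(4.0)

    def test_identical_conditions_all_null(self):
        rng = np.random.default_rng(0)
        placebo = rng.standard_normal((5, 3, 3))
        t, p, mean, _ = paired_edge_tests(placebo, placebo.copy())
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(mean[off], 0.0)
        # zero-variance differences are flagged undefined, not zero
        assert np.all(np.isnan(t[off]))

    def test_agrees_with_scipy_paired_test(self):
        rng = np.random.default_rng(3)
        placebo = rng.standard_normal((12, 4, 4))
        drug = placebo + rng.standard_normal((12, 4, 4)) * 0.3
        t, p, _, df = paired_edge_tests(placebo, drug)
        ref = sps.ttest_rel(drug, placebo, axis=0)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(t[off], ref.statistic[off], atol=1e-10)
        assert np.allclose(p[off], ref.pvalue[off], atol=1e-10)

    def test_too_few_subjects_rejected(self):
        placebo, drug = _grids_from_diffs([1.0, 2.0])
        with pytest.raises(ValueError, match="3 subjects"):
            paired_edge_tests(placebo, drug)

    def test_adding_constant_increases_delta_mean(self):
        rng = np.random.default_rng(5)
        placebo = rng.standard_normal((6, 3, 3))
        drug = rng.standard_normal((6, 3, 3))
        _, _, base, _ = paired_edge_tests(placebo, drug)
        _, _, shifted, _ = paired_edge_tests(placebo, drug + 0.5)
        assert np.all(shifted >= base)


def brute_force_bh(p, alpha):
    """Independent literal step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * alpha:
            k = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q, reject


class TestBHFDR:
    def test_worked_step_up_example(self):
        p = np.array([0.01, 0.02, 0.04, 0.5])
        q, reject = bh_fdr(p, alpha=0.05)
        assert reject.tolist() == [True, True, False, False]

    def test_all_ones(self):
        q, reject = bh_fdr(np.ones(10))
        assert not reject.any()
        assert np.allclose(q, 1.0)

    def test_single_p_identity(self):
        q, reject = bh_fdr(np.array([0.04]), alpha=0.05)
        assert reject[0]
        assert q[0] == pytest.approx(0.04)

    def test_empty_input(self):
        q, reject = bh_fdr(np.array([]))
        assert q.size == 0 and reject.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            q, reject = bh_fdr(p, alpha=0.05)
            q_ref, reject_ref = brute_force_bh(p, 0.05)
            assert np.array_equal(reject, reject_ref)
            assert np.allclose(q, q_ref, atol=1e-12)

    def test_nan_entries_excluded_from_family(self):
        p = np.array([0.001, np.nan, 0.9])
        q, reject = bh_fdr(p)
        assert np.isnan(q[1]) and not reject[1]
        assert reject[0]


class TestExtractDifferenceMatrix:
    def _grids(self, n):
        rng = np.random.default_rng(11)
        t = rng.standard_normal((n, n))
        t = (t + t.T) / 2
        p = 2 * sps.norm.sf(np.abs(t))
        np.fill_diagonal(t, np.nan)
        np.fill_diagonal(p, np.nan)
        return t, p

    def test_atlas_scale_shape(self, paper_parcellation):
        assigned = paper_parcellation.assigned_nodes
        t, p = self._grids(assigned.size)
        diff = extract_difference_matrix(
            t, p, t * 0.1, 54, assigned, paper_parcellation
        )
        assert diff.shape == (65, 223)

    def test_toy_shape(self, toy_parcellation):
        assigned = toy_parcellation.assigned_nodes
        t, p = self._grids(assigned.size)
        diff = extract_difference_matrix(t, p, t * 0.1, 9, assigned, toy_parcellation)
        assert diff.shape == (3, 5)

    def test_no_dmn_dmn_or_unassigned_columns(self, toy_parcellation):
        assigned = toy_parcellation.assigned_nodes
        t, p = self._grids(assigned.size)
        diff = extract_difference_matrix(t, p, t * 0.1, 9, assigned, toy_parcellation)
        dmn = set(toy_parcellation.dmn_nodes.tolist())
        unassigned = {8, 9}
        assert not (set(diff.cols.tolist()) & (dmn | unassigned))
        assert set(diff.rows.tolist()) == dmn

    def test_mask_respects_alpha(self, toy_parcellation):
        assigned = toy_parcellation.assigned_nodes
        t, p = self._grids(assigned.size)
        diff = extract_difference_matrix(t, p, t * 0.1, 9, assigned, toy_parcellation)
        assert np.all(diff.q[diff.mask] <= diff.alpha)


class TestNetworkwise:
    def test_symmetric_values_null(self):
        diff = make_diff(np.array([[2.0, -2.0]]), col_networks=("Aud", "Aud"))
        parc = pc.Parcellation(
            node_id=np.arange(3), label=("a", "b", "c"),
            network=("DefaultMode", "Aud", "Aud"), dmn_name="DefaultMode",
        )
        res = networkwise_tests(diff, parc)
        assert res[0].t == pytest.approx(0.0)

    def test_hand_closed_form(self):
        diff = make_diff(np.array([[2.0, 4.0, 6.0]]), col_networks=("Aud",) * 3)
        parc = pc.Parcellation(
            node_id=np.arange(4), label=tuple("abcd"),
            network=("DefaultMode", "Aud", "Aud", "Aud"), dmn_name="DefaultMode",
        )
        res = networkwise_tests(diff, parc)
        # delta_mean = [0.1, 0.2, 0.3]: t = 0.2 / (0.1 / sqrt(3)) = 2 sqrt(3)
        assert res[0].t == pytest.approx(3.4641, abs=1e-4)
        assert res[0].df == 2
        assert res[0].p_bonf == pytest.approx(min(1.0, res[0].p_uncorrected * 1))

    def test_no_survivors_not_testable(self):
        diff = make_diff(
            np.array([[2.0, 3.0]]),
            mask=np.zeros((1, 2), dtype=bool),
            col_networks=("Aud", "Aud"),
        )
        parc = pc.Parcellation(
            node_id=np.arange(3), label=("a", "b", "c"),
            network=("DefaultMode", "Aud", "Aud"), dmn_name="DefaultMode",
        )
        res = networkwise_tests(diff, parc)
        assert not res[0].testable
        assert res[0].n_edges == 0

    def test_bonferroni_factor_from_parcellation(self, toy_run):
        report, result = toy_run
        n_targets = len(result.parcellation.target_networks)
        assert n_targets == 3
        for r in result.network_results:
            if r.testable:
                assert r.p_bonf == pytest.approx(
                    min(1.0, r.p_uncorrected * n_targets)
                )
                assert r.df == r.n_edges - 1


class TestOverall:
    def test_symmetric_pairs_null(self):
        diff = make_diff(np.array([[2.0, -2.0, 1.0, -1.0]]))
        res = overall_test(diff)
        assert res.t == pytest.approx(0.0)

    def test_hand_closed_form(self):
        # values [-0.2, -0.1, -0.3, -0.2]: mean -0.2, sd 0.0816 -> t = -8 halved..
        diff = make_diff(np.array([[-4.0, -2.0, -6.0, -4.0]]))
        res = overall_test(diff)  # delta_mean = t * 0.05 = [-0.2,-0.1,-0.3,-0.2]
        assert res.t == pytest.approx(-0.2 / (np.std([-0.2, -0.1, -0.3, -0.2], ddof=1) / 2), abs=1e-10)
        assert res.t == pytest.approx(-4.8989794855, abs=1e-6)
        assert res.df == 3

    def test_fewer_than_two_survivors_not_testable(self):
        diff = make_diff(np.array([[1.0, 2.0]]), mask=np.array([[True, False]]))
        assert not overall_test(diff).testable

    def test_negative_on_decrease_dominated_scenario(self, toy_run):
        report, _ = toy_run
        assert report["overall_test"]["t"] < 0


class TestFDRControlUnderNull:
    def test_empirical_fdr_at_nominal_level(self):
        """Full-null edge-level simulation: expected FDP <= alpha + 2 MC-SE."""
        rng = np.random.default_rng(2024)
        n_sub, m = 12, 300
        fdps = []
        for _ in range(200):
            d = rng.standard_normal((n_sub, m))
            t = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(n_sub))
            p = 2 * sps.t.sf(np.abs(t), n_sub - 1)
            _, reject = bh_fdr(p, alpha=0.05)
            # every hypothesis is null, so FDP is 1 whenever anything rejects
            fdps.append(1.0 if reject.any() else 0.0)
        fdps = np.asarray(fdps, dtype=float)
        mc_se = fdps.std(ddof=1) / np.sqrt(len(fdps))
        assert fdps.mean() <= 0.05 + 2 * mc_se
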