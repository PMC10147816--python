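"""Semi-partial correlation, Fisher transform, group stats and thresholding."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dogconn as dc
from dogconn.connectivity import P_SENTINEL
from dogconn.errors import InsufficientDataError, SingularMatrixError

from conftest import brute_bh_stepup, brute_semipartial


def _ts(X, names=None):
    names = names or tuple(f"r{i}" for i in range(X.shape[1]))
    return dc.ROITimeSeries("s0", np.asarray(X, float), tuple(names))


class TestSemipartial:
    def test_identical_signals_give_unit_correlation(self):
        x = np.random.default_rng(0).standard_normal(50)
        sc = dc.semipartial_matrix(_ts(np.column_stack([x, x])))
        assert sc.r[0, 1] == pytest.approx(1.0)

    def test_orthogonal_signals_give_zero(self):
        q, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((30, 3)))
        sc = dc.semipartial_matrix(_ts(q))
        off = sc.r[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-10)

    def test_matches_bruteforce_on_known_covariance(self):
        rng = np.random.default_rng(7)
        cov = np.array(
            [[1, 0.5, 0.2, 0.0], [0.5, 1, 0.3, 0.1], [0.2, 0.3, 1, 0.4], [0.0, 0.1, 0.4, 1]]
        )
        X = rng.multivariate_normal(np.zeros(4), cov, size=200)
        sc = dc.semipartial_matrix(_ts(X))
        np.testing.assert_allclose(sc.r, brute_semipartial(X), atol=1e-10)

    def test_diagonal_covariance_converges_to_zero(self):
        X = np.random.default_rng(3).standard_normal((5000, 6))
        sc = dc.semipartial_matrix(_ts(X))
        assert np.abs(sc.r[~np.eye(6, dtype=bool)]).max() < 0.05

    def test_too_few_timepoints_rejected(self):
        X = np.random.default_rng(0).standard_normal((4, 6))
        with pytest.raises(InsufficientDataError):
            dc.semipartial_matrix(_ts(X))

    def test_rank_deficiency_reported(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        X = np.column_stack([a, b, a + b, rng.standard_normal(50)])
        with pytest.raises(SingularMatrixError):
            dc.semipartial_matrix(_ts(X))


class TestFisher:
    def test_zero_maps_to_zero(self):
        assert dc.fisher_z(0.0) == 0.0

    def test_log_form_oracle(self):
        r = 0.5
        assert dc.fisher_z(r) == pytest.approx(math.log((1 + r) / (1 - r)) / 2)
        assert dc.fisher_z(r) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_symmetry(self):
        r = np.linspace(-0.9, 0.9, 19)
        np.testing.assert_allclose(dc.fisher_z(-r), -dc.fisher_z(r))

    def test_degenerate_correlation_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            z = dc.fisher_z(1.0)
        assert np.isfinite(z)


def _subject(r, names, sid="s"):
    r = np.asarray(r, float)
    return dc.SubjectConnectivity(sid, tuple(names), r)


class TestGroupStats:
    def test_all_zero_cohort(self):
        names = ("a", "b", "c")
        cohort = [_subject(np.zeros((3, 3)), names, f"s{i}") for i in range(5)]
        gs = dc.group_edge_stats(cohort, n_perm=200, seed=0)
        assert np.all(gs.t == 0)
        iu = np.triu_indices(3, k=1)
        assert np.all(gs.p_edge[iu] == 1.0)
        assert np.all(gs.p_seed == 1.0)

    def test_t_matches_closed_form(self):
        rng = np.random.default_rng(4)
        names = ("a", "b", "c")
        zvals = rng.normal(0.3, 0.2, size=10)
        cohort = []
        for i, z in enumerate(zvals):
            r = np.zeros((3, 3))
            r[0, 1] = r[1, 0] = np.tanh(z)
            cohort.append(_subject(r, names, f"s{i}"))
        gs = dc.group_edge_stats(cohort, n_perm=100, seed=0)
        expect = zvals.mean() / (zvals.std(ddof=1) / math.sqrt(10))
        assert gs.t[0, 1] == pytest.approx(expect, rel=1e-10)

    def test_zero_variance_sentinel(self):
        names = ("a", "b", "c")
        r = np.zeros((3, 3))
        r[0, 1] = r[1, 0] = np.tanh(0.5)
        cohort = [_subject(r, names, f"s{i}") for i in range(6)]
        with pytest.warns(UserWarning, match="zero-variance"):
            gs = dc.group_edge_stats(cohort, n_perm=100, seed=0)
        assert gs.p_edge[0, 1] == P_SENTINEL
        assert 0 < gs.p_edge[0, 1] <= 1

    def test_mismatched_roi_order_rejected(self):
        a = _subject(np.zeros((3, 3)), ("a", "b", "c"))
        b = _subject(np.zeros((3, 3)), ("c", "b", "a"))
        with pytest.raises(dc.errors.AlignmentError):
            dc.group_edge_stats([a, b, a], n_perm=10)


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert dc.bh_fdr([0.01]) == pytest.approx([0.01])

    def test_stepup_example(self):
        np.testing.assert_allclose(dc.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(dc.bh_fdr([0.2] * 5), [0.2] * 5)

    def test_empty(self):
        assert len(dc.bh_fdr([])) == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_matches_bruteforce_and_order_invariant(self, ps):
        q = dc.bh_fdr(ps)
        np.testing.assert_allclose(q, brute_bh_stepup(ps), atol=1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = dc.bh_fdr([ps[i] for i in perm])
        np.testing.assert_allclose(np.asarray(q)[perm], q_perm, atol=1e-12)


def _stats_4roi(p_edge, q_seed, t=None):
    names = ("a", "b", "c", "d")
    p = np.ones((4, 4))
    iu = np.triu_indices(4, k=1)
    p[iu] = p_edge
    p = np.minimum(p, p.T)
    tm = np.full((4, 4), 2.5) if t is None else t
    return dc.GroupEdgeStats(
        names, mean_z=np.full((4, 4), 0.3), t=tm, p_edge=p,
        p_seed=np.asarray(q_seed), q_seed=np.asarray(q_seed), n_subjects=10, n_perm=100,
    )


class TestThreshold:
    def test_all_null_gives_empty_graph(self):
        gs = _stats_4roi([1.0] * 6, [1.0] * 4)
        assert len(dc.threshold_edges(gs)) == 0

    def test_retention_predicate_by_enumeration(self):
        # edges: ab, ac, ad, bc, bd, cd; only seeds a and c pass FDR
        p_edge = [0.001, 0.5, 0.005, 0.005, 0.005, 0.5]
        q_seed = [0.01, 0.9, 0.02, 0.9]
        got = dc.threshold_edges(_stats_4roi(p_edge, q_seed))
        kept = set(zip(got["roi_i"], got["roi_j"]))
        # ab: p ok, seed a ok -> keep; ad: p ok, seed a ok -> keep
        # bc: p ok, seed c ok -> keep; bd: p ok, neither seed -> drop
        assert kept == {("a", "b"), ("a", "d"), ("b", "c")}

    def test_everything_significant_gives_complete_graph(self):
        gs = _stats_4roi([1e-6] * 6, [1e-6] * 4)
        assert len(dc.threshold_edges(gs)) == 6

    def test_monotone_in_edge_alpha(self):
        rng = np.random.default_rng(2)
        p_edge = rng.uniform(0, 0.05, 6)
        gs = _stats_4roi(p_edge, [0.01] * 4)
        loose = dc.threshold_edges(gs, edge_alpha=0.04)
        tight = dc.threshold_edges(gs, edge_alpha=0.01)
        loose_set = set(zip(loose["roi_i"], loose["roi_j"]))
        tight_set = set(zip(tight["roi_i"], tight["roi_j"]))
        assert tight_set <= loose_set


class TestOracleEquivalence:
    def test_random_instances_match_bruteforce(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            p = int(rng.integers(4, 9))
            X = rng.standard_normal((int(rng.integers(30, 80)), p))
            got = dc.semipartial_matrix(_ts(X)).r
            np.testing.assert_allclose(got, brute_semipartial(X), atol=1e-8)
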