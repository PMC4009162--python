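"""Exact, series, and Monte-Carlo mean first passage times."""

import numpy as np
import pytest

from celldiff3d.dynamics import find_attractors
from celldiff3d.network_model import parse_network
from celldiff3d.noise_kernel import TransitionKernel
from celldiff3d.mfpt import (
    estimate_mfpt_mc,
    fk_series,
    hitting_times,
    mfpt_attractors,
    mfpt_tsv,
    series_mfpt,
)
from celldiff3d.fixtures import RandomNetSpec, random_network


class TestHittingTimes:
    def test_geometric_escape_is_inverse_p(self, nets):
        kernel = TransitionKernel(nets["identity-1"], 0.01)
        k = hitting_times(kernel, [1])
        assert k[0] == pytest.approx(100.0, rel=1e-10)
        assert k[1] == 0.0

    def test_two_gene_first_step_system(self, nets):
        # closed form for identity-2, p=0.1, target 11: the two-unknown
        # system 0.19 a = 1 + 0.18 b, 0.18 b = 1 + 0.09 a gives a = 20
        kernel = TransitionKernel(nets["identity-2"], 0.1)
        k = hitting_times(kernel, [3])
        assert k[0] == pytest.approx(20.0, rel=1e-10)
        assert k[1] == pytest.approx(140.0 / 9.0, rel=1e-10)
        assert k[3] == 0.0

    def test_target_states_have_zero_hitting_time(self):
        net = random_network(RandomNetSpec(n=4, k=2, bias=0.5, seed=1))
        kernel = TransitionKernel(net, 0.05)
        k = hitting_times(kernel, [2, 9, 11])
        assert k[2] == k[9] == k[11] == 0.0
        others = np.delete(k, [2, 9, 11])
        assert np.all(others > 0)

    def test_matrix_free_route_matches_dense(self):
        net = random_network(RandomNetSpec(n=5, k=2, bias=0.5, seed=7))
        dense = hitting_times(TransitionKernel(net, 0.05), [0])
        lazy = hitting_times(TransitionKernel(net, 0.05, dense_limit=0), [0])
        assert np.allclose(dense, lazy, rtol=1e-8)


class TestMfptAttractors:
    @pytest.mark.parametrize("p", [0.5, 0.1, 0.01, 0.001])
    def test_identity_one_gene_equals_inverse_p(self, nets, p):
        kernel = TransitionKernel(nets["identity-1"], p)
        aset = find_attractors(nets["identity-1"])
        M = mfpt_attractors(kernel, aset)
        assert M.values[0, 1] == pytest.approx(1.0 / p, rel=1e-9)
        assert M.values[1, 0] == pytest.approx(1.0 / p, rel=1e-9)
        assert M.values[0, 0] == M.values[1, 1] == 0.0

    def test_smaller_p_never_decreases_mfpt(self, nets):
        aset = find_attractors(nets["identity-2"])
        prev = None
        for p in (0.5, 0.1, 0.01, 0.001):
            M = mfpt_attractors(TransitionKernel(nets["identity-2"], p), aset)
            if prev is not None:
                off = ~np.eye(aset.m, dtype=bool)
                assert np.all(M.values[off] >= prev[off])
            prev = M.values

    def test_single_attractor_gives_zero_matrix(self):
        net = parse_network("targets, factors\nA, 1\n")
        aset = find_attractors(net)
        assert aset.m == 1
        M = mfpt_attractors(TransitionKernel(net, 0.01), aset)
        assert M.values.shape == (1, 1) and M.values[0, 0] == 0.0

    def test_cyclic_source_averages_over_cycle_states(self, nets):
        net = nets["swap-2"]  # attractors {00}, {01,10}, {11}
        kernel = TransitionKernel(net, 0.1)
        aset = find_attractors(net)
        M = mfpt_attractors(kernel, aset)
        k = hitting_times(kernel, [0])
        assert M.values[1, 0] == pytest.approx((k[1] + k[2]) / 2.0, rel=1e-12)

    def test_tsv_export_has_metadata_and_labels(self, nets):
        net = nets["identity-1"]
        M = mfpt_attractors(TransitionKernel(net, 0.01), find_attractors(net))
        text = mfpt_tsv(M, {"seed": 0})
        assert "# p=0.01" in text and "# seed=0" in text
        assert text.count("attractor-") >= 2


class TestFkSeries:
    def test_geometric_first_passage_distribution(self, nets):
        kernel = TransitionKernel(nets["identity-1"], 0.01)
        res = fk_series(kernel, 0, [1], K=3000)
        ks = np.arange(1, 11)
        expected = 0.99 ** (ks - 1) * 0.01
        assert np.allclose(res.F[:10], expected, rtol=1e-12)
        assert res.partial_mfpt == pytest.approx(100.0, rel=1e-4)
        assert res.tail_mass < 1e-9

    def test_source_inside_target_is_already_arrived(self, nets):
        kernel = TransitionKernel(nets["identity-1"], 0.01)
        res = fk_series(kernel, 1, [1], K=50)
        assert np.all(res.F == 0.0) and res.partial_mfpt == 0.0

    def test_total_mass_reaches_one(self):
        net = random_network(RandomNetSpec(n=4, k=2, bias=0.5, seed=5))
        kernel = TransitionKernel(net, 0.1)
        res = fk_series(kernel, 0, [2**4 - 1], K=20_000)
        assert res.F.sum() == pytest.approx(1.0, abs=1e-9)

    def test_partial_sum_lower_bounds_exact(self):
        net = random_network(RandomNetSpec(n=4, k=2, bias=0.5, seed=5))
        kernel = TransitionKernel(net, 0.05)
        exact = hitting_times(kernel, [3])[0]
        res = fk_series(kernel, 0, [3], K=200)
        assert res.partial_mfpt + res.K * res.tail_mass <= exact + 1e-9

    @pytest.mark.parametrize("seed", range(6))
    def test_doubling_series_agrees_with_linear_solve(self, seed):
        net = random_network(RandomNetSpec(n=5, k=2, bias=0.5, seed=60 + seed))
        kernel = TransitionKernel(net, 0.05)
        target = [0, 1]
        exact = hitting_times(kernel, target)
        partial, tail, K = series_mfpt(kernel, target, tail_tol=1e-8)
        assert np.max(tail) < 1e-8
        nz = exact > 0
        assert np.allclose(partial[nz], exact[nz], rtol=1e-3)

    def test_doubling_matches_explicit_recursion(self, nets):
        kernel = TransitionKernel(nets["identity-2"], 0.1)
        res = fk_series(kernel, 0, [3], K=4096)
        partial, tail, K = series_mfpt(kernel, [3], tail_tol=1e-9)
        assert partial[0] == pytest.approx(res.partial_mfpt, rel=1e-9)


class TestMonteCarlo:
    def test_identity_one_gene_matches_closed_form(self, nets):
        est = estimate_mfpt_mc(
            nets["identity-1"], 0.01, [0], [1], n_walks=10_000, seed=11
        )
        assert abs(est.mean - 100.0) <= 3 * est.se
        assert est.n_censored == 0

    def test_two_gene_matches_linear_solve(self, nets):
        est = estimate_mfpt_mc(
            nets["identity-2"], 0.1, [0], [3], n_walks=10_000, seed=12
        )
        assert abs(est.mean - 20.0) <= 3 * est.se

    def test_seed_determinism(self, nets):
        a = estimate_mfpt_mc(nets["identity-1"], 0.05, [0], [1], 500, seed=3)
        b = estimate_mfpt_mc(nets["identity-1"], 0.05, [0], [1], 500, seed=3)
        assert a == b

    def test_censoring_reported_and_all_censored_raises(self, nets):
        with pytest.raises(RuntimeError, match="censored"):
            estimate_mfpt_mc(
                nets["identity-1"], 0.001, [0], [1], n_walks=50,
                max_steps=1, seed=0,
            )
        est = estimate_mfpt_mc(
            nets["identity-1"], 0.01, [0], [1], n_walks=2000,
            max_steps=120, seed=5,
        )
        assert 0 < est.n_censored < 2000

    def test_accepts_attractor_objects(self, nets):
        aset = find_attractors(nets["identity-1"])
        est = estimate_mfpt_mc(
            nets["identity-1"], 0.1, aset.attractors[0], aset.attractors[1],
            n_walks=2000, seed=4,
        )
        assert abs(est.mean - 10.0) <= 3 * est.se
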