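import numpy as np
import pytest

from fedmorph.design import InstitutionShard
from fedmorph.federation import (
    Federation,
    GradientMessage,
    ProtocolError,
    aggregate,
    local_gradient,
)
from fedmorph.oracle import prox_gradient_solve
from fedmorph.solver import SolverConfig, fbcd_solve, group_soft_threshold, objective

from helpers import flat_instance, full_objective


class TestGroupSoftThreshold:
    def test_full_shrinkage(self):
        assert np.array_equal(group_soft_threshold(np.array([1.0, 2.0]), 10.0), [0, 0])

    def test_no_penalty(self):
        z = np.array([1.0, -2.0, 0.5])
        assert np.array_equal(group_soft_threshold(z, 0.0), z)

    def test_hand_computed(self):
        out = group_soft_threshold(np.array([3.0, 4.0]), 2.5)
        assert np.allclose(out, [1.5, 2.0])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            group_soft_threshold(np.array([1.0]), -0.1)


class TestLocalGradient:
    def test_zero_beta_gives_minus_xty(self):
        X, y, cols, w, shards = flat_instance(0, n=30, n_groups=5, group_size=3)
        g = local_gradient(shards[0], np.zeros(X.shape[1]), cols[2])
        expected = -shards[0].X_i[:, cols[2]].T @ shards[0].y_i
        assert np.allclose(g, expected)

    def test_hand_computed_single_row(self):
        shard = InstitutionShard(0, np.array([[1.0, 2.0]]), np.array([1.0]), np.array([0]))
        g = local_gradient(shard, np.array([1.0, 1.0]), np.array([0, 1]))
        assert np.allclose(g, [2.0, 4.0])  # residual 2; gradient (2, 4)

    def test_dimension_mismatch(self):
        shard = InstitutionShard(0, np.ones((2, 3)), np.ones(2), np.arange(2))
        with pytest.raises(ValueError):
            local_gradient(shard, np.ones(5), np.array([0]))

    def test_shard_sum_equals_centralized(self):
        X, y, cols, w, shards = flat_instance(1, n=50, n_groups=8, group_size=2, n_sites=3)
        beta = np.random.default_rng(2).standard_normal(X.shape[1])
        total = sum(local_gradient(s, beta, cols[4]) for s in shards)
        assert np.allclose(total, X[:, cols[4]].T @ (X @ beta - y))


class TestAggregate:
    def test_identity_and_cancellation(self):
        m = GradientMessage(0, 3, np.array([1.0, 2.0]))
        assert np.array_equal(aggregate([m]), [1.0, 2.0])
        m2 = GradientMessage(1, 3, np.array([-1.0, -2.0]))
        assert np.array_equal(aggregate([m, m2]), [0.0, 0.0])

    def test_matches_direct_sum(self):
        rng = np.random.default_rng(5)
        parts = [rng.standard_normal(4) for _ in range(3)]
        msgs = [GradientMessage(i, 0, p) for i, p in enumerate(parts)]
        assert np.allclose(aggregate(msgs), np.sum(parts, axis=0))

    def test_missing_site_named(self):
        msgs = [GradientMessage(0, 0, np.zeros(2)), GradientMessage(2, 0, np.zeros(2))]
        with pytest.raises(ProtocolError, match="1"):
            aggregate(msgs, expected_sites=[0, 1, 2])


class TestObjective:
    def test_zero_beta(self):
        X, y, cols, w, shards = flat_instance(3, n=40, n_groups=6, group_size=2)
        assert objective(shards, np.zeros(X.shape[1]), 1.0, cols, w) == pytest.approx(
            0.5 * y @ y
        )

    def test_hand_computed(self):
        shard = InstitutionShard(0, np.array([[1.0, 0.0]]), np.array([2.0]), np.array([0]))
        val = objective([shard], np.array([1.0, 0.0]), 1.0, [np.array([0, 1])], [1.0])
        assert val == pytest.approx(1.5)  # 0.5*(2-1)^2 + 1*1

    def test_partition_invariant(self):
        X, y, cols, w, shards1 = flat_instance(4, n=60, n_groups=10, group_size=3)
        *_, shards4 = flat_instance(4, n=60, n_groups=10, group_size=3, n_sites=4)
        beta = np.random.default_rng(0).standard_normal(X.shape[1])
        a = objective(shards1, beta, 2.0, cols, w)
        b = objective(shards4, beta, 2.0, cols, w)
        assert a == pytest.approx(b, rel=1e-12)


class TestFBCD:
    def test_lambda_max_gives_zero_solution(self):
        _, _, cols, w, shards = flat_instance(6, n=50, n_groups=12, group_size=2)
        sol = fbcd_solve(shards, cols, w, SolverConfig(lambda_rel=1.0))
        assert np.all(sol.beta == 0)
        assert sol.epochs_run <= 2

    def test_orthonormal_single_group_closed_form(self):
        """With X_g^T X_g = I the solver's fixed point is one proximal step."""
        rng = np.random.default_rng(7)
        Q, _ = np.linalg.qr(rng.standard_normal((20, 3)))
        y = rng.standard_normal(20)
        shards = [InstitutionShard(0, Q, y, np.arange(20))]
        cols = [np.arange(3)]
        lam = 0.3 * np.linalg.norm(Q.T @ y)
        sol = fbcd_solve(shards, cols, [1.0], SolverConfig(tol=1e-14), lam=lam)
        expected = group_soft_threshold(Q.T @ y, lam)
        assert np.allclose(sol.beta, expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_centralized_oracle(self, seed):
        X, y, cols, w, shards = flat_instance(40 + seed, n_sites=2, n_groups=30)
        cfg = SolverConfig(tol=1e-12, max_epochs=5000)
        fed = Federation(shards, cols)
        sol = fbcd_solve(fed, weights=w, config=cfg, lam_max=None)
        oracle = prox_gradient_solve(X, y, cols, w, sol.lam, tol=1e-13)
        gap = abs(
            full_objective(X, y, sol.beta, sol.lam, cols, w)
            - full_objective(X, y, oracle, sol.lam, cols, w)
        )
        assert gap <= 1e-6

    def test_monotone_descent(self):
        """Cyclic proximal BCD never increases the objective across epochs."""
        X, y, cols, w, shards = flat_instance(77, n=60, n_groups=20, group_size=3)
        lam_objs = []
        for epochs in range(1, 8):
            sol = fbcd_solve(
                shards, cols, w,
                SolverConfig(lambda_rel=0.3, tol=1e-16, max_epochs=epochs),
            )
            lam_objs.append(sol.objective)
        assert all(a >= b - 1e-12 for a, b in zip(lam_objs, lam_objs[1:]))

    def test_federated_invariance_small(self):
        """Identical solutions under 1-, 3-, and 5-site row partitions."""
        X, y, cols, w, _ = flat_instance(9, n=90, n_groups=15, group_size=4)
        sols = {}
        rng = np.random.default_rng(1)
        for I in (1, 3, 5):
            perm = rng.permutation(len(y))
            shards = [
                InstitutionShard(i, X[idx], y[idx], idx)
                for i, idx in enumerate(np.array_split(perm, I))
            ]
            sols[I] = fbcd_solve(
                shards, cols, w, SolverConfig(lambda_rel=0.2, tol=1e-13, max_epochs=5000)
            )
        for I in (3, 5):
            assert sols[I].objective == pytest.approx(sols[1].objective, abs=1e-8)
            assert np.max(np.abs(sols[I].beta - sols[1].beta)) < 1e-6

    def test_kkt_certificate(self):
        X, y, cols, w, shards = flat_instance(13, n=80, n_groups=25, group_size=2)
        sol = fbcd_solve(shards, cols, w, SolverConfig(lambda_rel=0.3, tol=1e-12, max_epochs=5000))
        corr = X.T @ (y - X @ sol.beta)
        for g, c in enumerate(cols):
            nrm = np.linalg.norm(corr[c])
            if np.linalg.norm(sol.beta[c]) == 0:
                assert nrm <= sol.lam * w[g] * (1 + 1e-6)
            else:
                assert nrm == pytest.approx(sol.lam * w[g], rel=1e-6)

    def test_privacy_contract_on_transport(self):
        """No message carries anything longer than a per-group aggregate."""
        X, y, cols, w, shards = flat_instance(21, n=50, n_groups=10, group_size=3, n_sites=3)
        fed = Federation(shards, cols, record=True)
        fbcd_solve(fed, weights=w, config=SolverConfig(lambda_rel=0.3))
        max_pg = max(len(c) for c in cols)
        assert fed.transport.log, "transport recorded no messages"
        n_rows = {s.n_subjects for s in shards}
        for site, gid, kind, shape in fed.transport.log:
            assert len(shape) <= 2
            if shape:
                assert shape[-1] <= max_pg
                assert shape[-1] not in n_rows or shape[-1] <= max_pg
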