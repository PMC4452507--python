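"""Sigmoid matrix factorization: initialization, loss, SGD updates, training."""

import math

import numpy as np
import pytest

from gsmf.mf import (
    LabeledPairSet,
    MatrixFactorization,
    init_model,
    init_model_random,
    loss,
    predict,
    sgd_epoch,
    train,
)
from gsmf.network import FeatureSpace


def _space(ids, X):
    return FeatureSpace(ids=list(ids), X=np.asarray(X, dtype=float))


def _model(A, B, lambda_reg=0.0, eta=2.0**-4):
    m = MatrixFactorization(k=np.asarray(A).shape[1], lambda_reg=lambda_reg, eta=eta)
    return m.warm_start(np.asarray(A, float), np.asarray(B, float))


def _sigmoid(z):
    return 1.0 / (1.0 + math.exp(-min(max(z, -30.0), 30.0)))


class TestInitModel:
    def test_copies_feature_rows_in_order(self):
        dr = _space(["d1", "d2"], [[1.0, 2.0], [3.0, 4.0]])
        di = _space(["s1"], [[5.0, 6.0]])
        m = init_model(dr, di)
        assert np.array_equal(m.A_, dr.X) and m.A_ is not dr.X
        assert np.array_equal(m.B_, di.X)
        assert m.drug_ids_ == ["d1", "d2"] and m.disease_ids_ == ["s1"]

    def test_k_mismatch_reports_both(self):
        dr = _space(["d"], np.zeros((1, 8)))
        di = _space(["s"], np.zeros((1, 32)))
        with pytest.raises(ValueError, match="k=8.*k=32"):
            init_model(dr, di)

    def test_random_init_bounded_and_seeded(self):
        a = init_model_random(5, 3, k=4, init_scale=0.1, seed=7)
        b = init_model_random(5, 3, k=4, init_scale=0.1, seed=7)
        assert np.array_equal(a.A_, b.A_) and np.array_equal(a.B_, b.B_)
        assert np.abs(a.A_).max() <= 0.1 and np.abs(a.B_).max() <= 0.1
        assert a.A_.shape == (5, 4) and a.B_.shape == (3, 4)


class TestPredict:
    def test_orthogonal_rows_give_half(self):
        m = _model([[1.0, 0.0]], [[0.0, 1.0]])
        assert predict(m, 0, 0) == 0.5

    def test_log3_dot_gives_three_quarters(self):
        m = _model([[math.log(3.0), 0.0]], [[1.0, 0.0]])
        assert predict(m, 0, 0) == pytest.approx(0.75, abs=1e-12)

    def test_strictly_inside_unit_interval_and_monotone(self):
        b = np.array([[1.0, 0.0]])
        dots = [-1e6, -3.0, 0.0, 3.0, 1e6]
        vals = [predict(_model([[d, 0.0]], b), 0, 0) for d in dots]
        assert all(0.0 < v < 1.0 for v in vals)
        assert vals == sorted(vals)

    def test_out_of_range_index_rejected(self):
        m = _model([[1.0]], [[1.0]])
        with pytest.raises(IndexError):
            predict(m, 1, 0)
        with pytest.raises(IndexError):
            predict(m, 0, -1)


class TestLoss:
    def test_single_sample_at_half(self):
        m = _model([[1.0, 0.0]], [[0.0, 1.0]], lambda_reg=0.0)
        s = LabeledPairSet.from_samples([(0, 0, 1)])
        assert loss(m, s) == pytest.approx(0.125, abs=1e-15)

    def test_matches_naive_per_sample_loop(self):
        rng = np.random.default_rng(17)
        A = rng.normal(size=(6, 4))
        B = rng.normal(size=(5, 4))
        lam = 2.0**-7
        m = _model(A, B, lambda_reg=lam)
        di = rng.integers(0, 6, 20)
        si = rng.integers(0, 5, 20)
        # distinct pairs required
        seen, keep = set(), []
        for t in range(20):
            if (di[t], si[t]) not in seen:
                seen.add((di[t], si[t]))
                keep.append(t)
        di, si = di[keep], si[keep]
        y = rng.integers(0, 2, len(keep)).astype(float)
        s = LabeledPairSet(drug_idx=di, disease_idx=si, labels=y)
        expect = 0.0
        for i, j, lab in zip(di, si, y):
            f = _sigmoid(float(A[i] @ B[j]))
            expect += 0.5 * ((lab - f) ** 2 + lam * (A[i] @ A[i] + B[j] @ B[j]))
        assert loss(m, s) == pytest.approx(expect, abs=1e-12)

    def test_perfect_fit_zero_reg_loss_vanishes(self):
        # huge dot products drive F -> labels, lambda = 0
        m = _model([[40.0], [-40.0]], [[1.0]], lambda_reg=0.0)
        s = LabeledPairSet.from_samples([(0, 0, 1), (1, 0, 0)])
        assert loss(m, s) < 1e-12


class TestSgdEpoch:
    def test_zero_error_zero_reg_is_fixed_point(self):
        # F = 0.5 and y = 0.5 is impossible with binary labels; use saturated fit
        m = _model([[40.0, 0.0]], [[1.0, 0.0]], lambda_reg=0.0)
        s = LabeledPairSet.from_samples([(0, 0, 1)])
        A0, B0 = m.A_.copy(), m.B_.copy()
        sgd_epoch(m, s, seed=0)
        assert np.allclose(m.A_, A0, atol=1e-10)
        assert np.allclose(m.B_, B0, atol=1e-10)

    def test_pure_decay_shrinks_by_one_minus_eta_lambda(self):
        lam, eta = 2.0**-7, 2.0**-4
        m = _model([[40.0, 0.0]], [[1.0, 0.0]], lambda_reg=lam, eta=eta)
        s = LabeledPairSet.from_samples([(0, 0, 1)])
        A0, B0 = m.A_.copy(), m.B_.copy()
        sgd_epoch(m, s, seed=0)
        # e ~ 0 at saturation: update reduces to weight decay
        assert np.allclose(m.A_, A0 * (1 - eta * lam), atol=1e-6)
        assert np.allclose(m.B_, B0 * (1 - eta * lam), atol=1e-6)

    def test_single_step_matches_hand_computation(self):
        a = np.array([0.3, -0.2])
        b = np.array([0.5, 0.4])
        y, lam, eta = 1.0, 0.01, 0.1
        m = _model([a], [b], lambda_reg=lam, eta=eta)
        sgd_epoch(m, LabeledPairSet.from_samples([(0, 0, int(y))]), seed=0)
        z = float(a @ b)
        F = 1.0 / (1.0 + math.exp(-z))
        g = (y - F) * F * (1 - F)
        a_new = a + eta * (g * b - lam * a)
        b_new = b + eta * (g * a - lam * b)  # pre-update a
        assert np.allclose(m.A_[0], a_new, atol=1e-15)
        assert np.allclose(m.B_[0], b_new, atol=1e-15)

    def test_update_direction_matches_finite_differences(self):
        """Analytic per-sample gradient vs central differences of the loss."""
        rng = np.random.default_rng(42)
        eps = 1e-6
        lam = 2.0**-7
        for trial in range(100):
            k = int(rng.integers(1, 5))
            a = rng.normal(scale=0.8, size=k)
            b = rng.normal(scale=0.8, size=k)
            y = float(rng.integers(0, 2))

            def per_sample_loss(av, bv):
                f = _sigmoid(float(av @ bv))
                return 0.5 * ((y - f) ** 2 + lam * (av @ av + bv @ bv))

            z = float(a @ b)
            F = 1.0 / (1.0 + math.exp(-z))
            g = (y - F) * F * (1 - F)
            grad_a = -(g * b - lam * a)  # gradient = -update direction
            grad_b = -(g * a - lam * b)
            for c in range(k):
                da = a.copy(); da[c] += eps
                da2 = a.copy(); da2[c] -= eps
                num = (per_sample_loss(da, b) - per_sample_loss(da2, b)) / (2 * eps)
                assert num == pytest.approx(grad_a[c], rel=1e-5, abs=1e-9)
                db = b.copy(); db[c] += eps
                db2 = b.copy(); db2[c] -= eps
                num = (per_sample_loss(a, db) - per_sample_loss(a, db2)) / (2 * eps)
                assert num == pytest.approx(grad_b[c], rel=1e-5, abs=1e-9)


class TestTrain:
    def _planted(self, seed=0, n_u=12, n_s=8, k=3):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(n_u, k))
        B = rng.normal(size=(n_s, k))
        Z = A @ B.T
        pairs = [(i, j, int(Z[i, j] > 0)) for i in range(n_u) for j in range(n_s)]
        return LabeledPairSet.from_samples(pairs)

    def test_huge_tolerance_runs_one_epoch(self):
        s = self._planted()
        m = init_model_random(12, 8, k=3, seed=1)
        m, trace = train(m, s, max_epochs=50, tol=1e9, seed=2)
        assert m.n_epochs_ == 1
        assert len(trace) == 2  # initial loss + one epoch

    def test_learns_separable_data(self):
        from gsmf.evaluation import roc_auc

        s = self._planted(seed=3)
        m = init_model_random(12, 8, k=3, lambda_reg=0.0, eta=0.25, seed=1)
        m, trace = train(m, s, max_epochs=300, tol=0.0, seed=2)
        X = np.column_stack([s.drug_idx, s.disease_idx])
        assert roc_auc(s.labels, m.predict_proba(X)) > 0.95
        # loss non-increasing after burn-in
        tail = trace[len(trace) // 3:]
        assert all(a >= b - 1e-6 for a, b in zip(tail, tail[1:]))
        assert trace[-1] < trace[0]

    def test_bit_identical_given_seed(self):
        s = self._planted(seed=5)
        runs = []
        for _ in range(2):
            m = init_model_random(12, 8, k=3, seed=9)
            m, _ = train(m, s, max_epochs=20, tol=0.0, seed=4)
            runs.append((m.A_.copy(), m.B_.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_empty_sample_set_is_fixed_point(self):
        m = init_model_random(4, 3, k=2, seed=0)
        A0, B0 = m.A_.copy(), m.B_.copy()
        m, trace = train(m, LabeledPairSet.from_samples([]), max_epochs=10, tol=0.0, seed=1)
        assert np.array_equal(m.A_, A0) and np.array_equal(m.B_, B0)

    def test_divergence_raises_with_epoch(self):
        s = self._planted(seed=6)
        m = init_model_random(12, 8, k=3, eta=1e12, init_scale=10.0, seed=1)
        with pytest.raises(FloatingPointError, match="epoch"):
            train(m, s, max_epochs=50, tol=0.0, seed=2)


class TestLabeledPairSet:
    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            LabeledPairSet.from_samples([(0, 0, 1), (0, 0, 0)])

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            LabeledPairSet.from_samples([(0, 0, 2)])

    def test_concat_and_subset_roundtrip(self):
        a = LabeledPairSet.from_samples([(0, 0, 1), (1, 1, 0)])
        b = LabeledPairSet.from_samples([(2, 0, 0)])
        c = a.concat(b)
        assert len(c) == 3
        assert c.subset(np.array([0, 1])).pairs() == a.pairs()
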