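import numpy as np
import pytest

from chromnpls import npls
from chromnpls.tensor import ChromatinTensor, ExpressionVector
from conftest import random_tensor


def centered(X, y):
    return X - X.mean(0), y - y.mean()


def cov2(t, y):
    n = len(y)
    return (float(t @ y) / (n - 1)) ** 2


def pls1_nipals(X, y, f):
    """Independent textbook PLS1 oracle: deflate X by t p', y by t q."""
    xc, yc = X.mean(0), y.mean()
    Xr, yr = X - xc, y - yc
    W, P, Q = [], [], []
    for _ in range(f):
        w = Xr.T @ yr
        w = w / np.linalg.norm(w)
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        q = yr @ t / (t @ t)
        Xr = Xr - np.outer(t, p)
        yr = yr - t * q
        W.append(w)
        P.append(p)
        Q.append(q)
    W, P, Q = np.column_stack(W), np.column_stack(P), np.array(Q)
    B = W @ np.linalg.solve(P.T @ W, Q)
    return lambda Xn: (Xn - xc) @ B + yc


class TestCrossCovMatrix:
    def test_linearity_and_single_gene(self, rng):
        X = rng.normal(size=(5, 3, 4))
        assert np.array_equal(npls.cross_cov_matrix(X, np.zeros(5)), np.zeros((3, 4)))
        one = rng.normal(size=(1, 3, 4))
        assert np.array_equal(npls.cross_cov_matrix(one, np.array([1.0])), one[0])

    def test_hand_summation(self):
        X = np.array(
            [[[1, 2], [3, 4]], [[5, 6], [7, 8]], [[-1, 0], [2, -2]]], dtype=float
        )
        y = np.array([2.0, -1.0, 3.0])
        expected = 2 * X[0] - X[1] + 3 * X[2]
        assert np.array_equal(npls.cross_cov_matrix(X, y), expected)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            npls.cross_cov_matrix(rng.normal(size=(5, 3, 4)), np.zeros(4))


class TestExtractComponent:
    def test_rank_one_construction_recovered(self, rank_one_data):
        X, yv, a, c = rank_one_data
        Xc, yc = centered(X.values, yv.y)
        comp = npls.extract_component(Xc, yc)
        assert abs(abs(comp.p1 @ a) - 1) < 1e-10
        assert abs(abs(comp.p2 @ c) - 1) < 1e-10
        r = np.corrcoef(comp.t, yv.y)[0, 1]
        assert abs(abs(r) - 1) < 1e-10

    def test_monte_carlo_maximization_oracle(self, rng):
        X, y = random_tensor(rng, n=50, J=4, K=6)
        Xc, yc = centered(X.values, y.y)
        comp = npls.extract_component(Xc, yc)
        U = rng.normal(size=(10_000, 4))
        V = rng.normal(size=(10_000, 6))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        t_all = np.einsum("ijk,mj,mk->mi", Xc, U, V)
        cov_all = (t_all @ yc) / (len(yc) - 1)
        assert comp.achieved_cov2 >= np.max(cov_all**2) - 1e-12

    def test_independent_svd_oracle(self, rng):
        # leading singular pair recovered from an eigen-decomposition of
        # Z'Z / ZZ', a route independent of np.linalg.svd
        X, y = random_tensor(rng, n=20, J=2, K=2)
        Xc, yc = centered(X.values, y.y)
        Z = npls.cross_cov_matrix(Xc, yc)
        comp = npls.extract_component(Xc, yc)
        from scipy.linalg import eigh

        evals_r, evecs_r = eigh(Z.T @ Z)
        p2_ref = evecs_r[:, -1]
        evals_l, evecs_l = eigh(Z @ Z.T)
        p1_ref = evecs_l[:, -1]
        assert abs(abs(comp.p1 @ p1_ref) - 1) < 1e-10
        assert abs(abs(comp.p2 @ p2_ref) - 1) < 1e-10

    def test_sign_convention(self, rng):
        for _ in range(5):
            X, y = random_tensor(rng)
            Xc, yc = centered(X.values, y.y)
            comp = npls.extract_component(Xc, yc)
            assert comp.p1[np.argmax(np.abs(comp.p1))] > 0
            assert comp.t @ yc >= 0

    def test_zero_cross_covariance_rejected(self):
        X = np.zeros((10, 2, 3))
        with pytest.raises(ValueError, match="uncorrelated"):
            npls.extract_component(X, np.arange(10.0) - 4.5)


class TestFit:
    def test_exact_recovery_rank_one(self, rank_one_data):
        X, yv, _, _ = rank_one_data
        model = npls.fit(X, yv, f=1)
        pred = npls.predict(model, X)
        assert np.allclose(pred.y, yv.y, atol=1e-6)

    @pytest.mark.parametrize("f", [1, 2, 3])
    def test_two_way_degeneration_matches_pls1(self, rng, f):
        # a singleton bin mode collapses the tensor to a matrix; predictions
        # must agree with an independently coded NIPALS PLS1
        n, J = 30, 6
        M = rng.normal(size=(n, J))
        y = rng.normal(size=n)
        Mn = rng.normal(size=(12, J))
        X = ChromatinTensor(
            values=M[:, :, None],
            gene_ids=[f"g{i}" for i in range(n)],
            mark_names=[f"m{j}" for j in range(J)],
            bin_offsets=np.array([0.0]),
        )
        Xn = ChromatinTensor(
            values=Mn[:, :, None],
            gene_ids=[f"h{i}" for i in range(12)],
            mark_names=X.mark_names,
            bin_offsets=np.array([0.0]),
        )
        yv = ExpressionVector(y=y, gene_ids=X.gene_ids)
        model = npls.fit(X, yv, f)
        ref = pls1_nipals(M, y, f)
        assert np.allclose(npls.predict(model, Xn).y, ref(Mn), atol=1e-8)

    def test_deflation_monotone_residual(self, rng):
        X, y = random_tensor(rng, n=40, J=4, K=6)
        Xc, ycen = centered(X.values, y.y)
        x_res, y_res = Xc.copy(), ycen.copy()
        T = []
        norms = [np.linalg.norm(x_res)]
        for _ in range(5):
            comp = npls.extract_component(x_res, y_res)
            T.append(comp.t)
            Tm = np.column_stack(T)
            b, *_ = np.linalg.lstsq(Tm, ycen, rcond=None)
            x_res = x_res - np.einsum("i,j,k->ijk", comp.t, comp.p1, comp.p2)
            y_res = ycen - Tm @ b
            norms.append(np.linalg.norm(x_res))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_unit_norm_loadings(self, rng):
        X, y = random_tensor(rng, n=40, J=4, K=6)
        model = npls.fit(X, y, f=4)
        assert np.allclose(np.linalg.norm(model.P1, axis=0), 1, atol=1e-10)
        assert np.allclose(np.linalg.norm(model.P2, axis=0), 1, atol=1e-10)

    def test_f_out_of_range(self, rng):
        X, y = random_tensor(rng, n=10, J=2, K=3)
        with pytest.raises(ValueError):
            npls.fit(X, y, 0)
        with pytest.raises(ValueError):
            npls.fit(X, y, 7)  # > I2*I3 = 6

    def test_degenerate_residual_reports_rank(self, rank_one_data):
        X, yv, _, _ = rank_one_data
        # rank-one data supports exactly one informative component
        with pytest.raises(ValueError, match="achievable rank is 1"):
            npls.fit(X, yv, f=3)

    def test_permutation_equivariance(self, rng):
        X, y = random_tensor(rng, n=30, J=3, K=5)
        model = npls.fit(X, y, f=3)
        perm = rng.permutation(30)
        model_p = npls.fit(X.subset_genes(perm), y.subset_genes(perm), f=3)
        assert np.allclose(model_p.T, model.T[perm], atol=1e-8)
        assert np.allclose(model_p.P1, model.P1, atol=1e-8)
        assert np.allclose(model_p.P2, model.P2, atol=1e-8)
        assert np.allclose(model_p.b, model.b, atol=1e-8)

    def test_affine_consistency(self, rng):
        X, y = random_tensor(rng, n=30, J=3, K=5)
        Xn, _ = random_tensor(rng, n=10, J=3, K=5)
        a, c = 2.5, -3.0
        y2 = ExpressionVector(y=a * y.y + c, gene_ids=y.gene_ids)
        p1 = npls.predict(npls.fit(X, y, 3), Xn).y
        p2 = npls.predict(npls.fit(X, y2, 3), Xn).y
        assert np.allclose(p2, a * p1 + c, atol=1e-8)


class TestPredict:
    def test_self_consistency_on_training_data(self, rng):
        X, y = random_tensor(rng, n=30, J=3, K=5)
        model = npls.fit(X, y, f=3)
        pred = npls.predict(model, X)
        T = npls._scores(model, X.values)
        assert np.allclose(T, model.T, atol=1e-10)
        assert np.allclose(pred.y, model.T @ model.b + model.y_center, atol=1e-10)

    def test_zero_coefficients_predict_center(self, rng):
        X, y = random_tensor(rng, n=20, J=3, K=4)
        model = npls.fit(X, y, f=2)
        model.b = np.zeros_like(model.b)
        pred = npls.predict(model, X)
        assert np.allclose(pred.y, model.y_center)

    def test_held_out_rank_one_generalization(self, rng):
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        c = rng.normal(size=5)
        c /= np.linalg.norm(c)
        y_all = rng.normal(size=60)
        values = y_all[:, None, None] * np.outer(a, c)[None]
        offsets = (np.arange(5) - 2).astype(float)
        ids = [f"g{i}" for i in range(60)]
        X_train = ChromatinTensor(values[:40], ids[:40], ["a", "b", "c"], offsets)
        X_test = ChromatinTensor(values[40:], ids[40:], ["a", "b", "c"], offsets)
        model = npls.fit(
            X_train, ExpressionVector(y=y_all[:40], gene_ids=ids[:40]), f=1
        )
        pred = npls.predict(model, X_test)
        assert np.allclose(pred.y, y_all[40:], atol=1e-6)

    def test_axis_mismatch_rejected(self, rng):
        X, y = random_tensor(rng, n=20, J=3, K=4)
        model = npls.fit(X, y, f=1)
        bad = ChromatinTensor(
            values=X.values,
            gene_ids=X.gene_ids,
            mark_names=["x", "y", "z"],
            bin_offsets=X.bin_offsets,
        )
        with pytest.raises(ValueError, match="mark"):
            npls.predict(model, bad)

    def test_model_json_round_trip(self, rng, tmp_path):
        X, y = random_tensor(rng, n=20, J=3, K=4)
        model = npls.fit(X, y, f=2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = npls.NPLSModel.from_json(path)
        assert np.allclose(back.P1, model.P1, atol=0)
        assert np.allclose(back.b, model.b, atol=0)
        assert np.allclose(npls.predict(back, X).y, npls.predict(model, X).y)


class TestSelectFactors:
    def test_rank_one_selects_one_factor(self, rng):
        # rank-one with slight noise so extra components remain extractable
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        c = rng.normal(size=4)
        c /= np.linalg.norm(c)
        y = rng.normal(size=60)
        values = y[:, None, None] * np.outer(a, c)[None]
        values += rng.normal(scale=1e-4, size=values.shape)
        X = ChromatinTensor(
            values,
            [f"g{i}" for i in range(60)],
            ["a", "b", "c"],
            (np.arange(4) - 1.5).astype(float),
        )
        yv = ExpressionVector(y=y, gene_ids=X.gene_ids)
        f_star, curve = npls.select_factors(X, yv, f_max=3, k=5, seed=0)
        assert f_star == 1
        assert len(curve) == 3

    def test_f_max_one(self, rng):
        X, y = random_tensor(rng, n=30, J=3, K=4)
        f_star, curve = npls.select_factors(X, y, f_max=1, k=5, seed=0)
        assert f_star == 1
        assert len(curve) == 1
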