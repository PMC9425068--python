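import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from gcnlmf.logmf import (
    AssociationData,
    LogisticMF,
    association_probability,
    confidence,
    grad_beta_i,
    grad_beta_u,
    grad_x_u,
    grad_y_i,
    load_model,
    log_posterior,
    rank_genes,
    save_model,
)


class TestAssociationProbability:
    def test_zero_score_is_half(self):
        assert association_probability(np.zeros(3), np.zeros(3)) == 0.5

    def test_log_three_gives_three_quarters(self):
        assert association_probability(
            np.array([1.0]), np.array([np.log(3)])
        ) == pytest.approx(0.75)

    def test_saturation_stays_inside_open_interval(self):
        p = association_probability(np.array([1000.0]), np.array([1.0]))
        assert 1 - 1e-12 < p < 1
        q = association_probability(np.array([-1000.0]), np.array([1.0]))
        assert 0 < q < 1e-12


class TestConfidence:
    def test_zero_observation_maps_to_one(self):
        assert confidence(0.0, a=5.0, epsilon=0.3) == 1.0

    def test_at_epsilon(self):
        assert confidence(1.0, a=2.0, epsilon=1.0) == pytest.approx(1 + 2 * np.log(2))

    def test_monotone_in_r(self):
        assert confidence(2.0, 1.0, 1.0) - confidence(1.0, 1.0, 1.0) == pytest.approx(
            np.log(3 / 2)
        )

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            confidence(1.0, 1.0, 0.0)


def _zeros(n, f):
    return np.zeros(f), np.zeros((n, f)), 0.0, np.zeros(n)


class TestLogPosterior:
    def test_single_negative_gene_all_zero_params(self):
        x, Y, bu, b = _zeros(1, 2)
        lp = log_posterior(AssociationData([0.0]), x, Y, bu, b, a=2.0, lam=0.0)
        assert lp == pytest.approx(-np.log(2))

    def test_additivity_over_genes(self):
        n = 7
        x, Y, bu, b = _zeros(n, 3)
        lp = log_posterior(AssociationData(np.zeros(n)), x, Y, bu, b, a=2.0, lam=0.0)
        assert lp == pytest.approx(-n * np.log(2))

    def test_penalty_term_is_exact(self, rng):
        n, f = 5, 3
        x = rng.standard_normal(f)
        Y = np.zeros((n, f))
        data = AssociationData(rng.integers(0, 2, n).astype(float))
        lam = 0.7
        lp0 = log_posterior(data, x, Y, 0.0, np.zeros(n), a=2.0, lam=0.0)
        lp1 = log_posterior(data, x, Y, 0.0, np.zeros(n), a=2.0, lam=lam)
        assert lp0 - lp1 == pytest.approx(0.5 * lam * (x @ x))

    def test_masked_genes_do_not_contribute(self, rng):
        r = np.array([1.0, 0.0, 1.0])
        Y = rng.standard_normal((3, 2))
        x = rng.standard_normal(2)
        full = log_posterior(AssociationData(r), x, Y, 0.1, np.zeros(3), a=2.0, lam=0.3)
        masked = log_posterior(
            AssociationData(r, mask=[True, True, False]),
            x, Y, 0.1, np.zeros(3), a=2.0, lam=0.3,
        )
        assert masked != pytest.approx(full)
        # masked 3-gene value equals the 2-gene problem's value exactly
        assert masked == pytest.approx(
            log_posterior(AssociationData(r[:2]), x, Y[:2], 0.1, np.zeros(2), a=2.0, lam=0.3)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            log_posterior(AssociationData([0.0, 1.0]), np.zeros(2), np.zeros((3, 2)), 0.0, np.zeros(3))


class TestGradients:
    def test_bias_gradient_at_zero_params(self):
        # sigma(0)=1/2 and r=0 everywhere: d/d beta_u = -N/2
        x, Y, bu, b = _zeros(4, 2)
        g = grad_beta_u(AssociationData(np.zeros(4)), x, Y, bu, b, a=2.0, lam=0.0)
        assert g == -2.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        f = int(rng.integers(1, 5))
        data = AssociationData(
            rng.integers(0, 2, n).astype(float), mask=rng.random(n) < 0.8
        )
        x = rng.standard_normal(f)
        Y = rng.standard_normal((n, f))
        bu = float(rng.standard_normal())
        b = rng.standard_normal(n)
        kw = dict(a=float(rng.uniform(0, 4)), lam=float(rng.uniform(0, 2)))
        h = 1e-6

        def lp(x_=None, Y_=None, bu_=None, b_=None):
            return log_posterior(
                data,
                x if x_ is None else x_,
                Y if Y_ is None else Y_,
                bu if bu_ is None else bu_,
                b if b_ is None else b_,
                **kw,
            )

        gx = grad_x_u(data, x, Y, bu, b, **kw)
        num = np.array(
            [(lp(x_=x + h * e) - lp(x_=x - h * e)) / (2 * h) for e in np.eye(f)]
        )
        assert np.linalg.norm(gx - num) <= 1e-5 * max(np.linalg.norm(num), 1.0)

        gbu = grad_beta_u(data, x, Y, bu, b, **kw)
        num_bu = (lp(bu_=bu + h) - lp(bu_=bu - h)) / (2 * h)
        assert abs(gbu - num_bu) <= 1e-5 * max(abs(num_bu), 1.0)

        i = int(rng.integers(0, n))
        gy = grad_y_i(data, x, Y, bu, b, i, **kw)
        num_y = []
        for j in range(f):
            Yp, Ym = Y.copy(), Y.copy()
            Yp[i, j] += h
            Ym[i, j] -= h
            num_y.append((lp(Y_=Yp) - lp(Y_=Ym)) / (2 * h))
        assert np.linalg.norm(gy - np.array(num_y)) <= 1e-5 * max(
            np.linalg.norm(num_y), 1.0
        )

        gb = grad_beta_i(data, x, Y, bu, b, i, **kw)
        bp, bm = b.copy(), b.copy()
        bp[i] += h
        bm[i] -= h
        num_b = (lp(b_=bp) - lp(b_=bm)) / (2 * h)
        assert abs(gb - num_b) <= 1e-5 * max(abs(num_b), 1.0)

    def test_vanish_at_independent_optimum(self):
        # 1 gene, f=1: maximize the posterior with derivative-free Nelder-Mead
        # and check the analytic gradients vanish there.
        data = AssociationData([1.0])
        a, lam = 2.0, 0.5

        def neg(theta):
            x, yv, bu, bi = theta
            return -log_posterior(
                data, [x], np.array([[yv]]), bu, np.array([bi]), a=a, lam=lam
            )

        res = minimize(
            neg, [0.1, 0.1, 0.0, 0.0], method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000, maxfev=20000),
        )
        x, yv, bu, bi = res.x
        args = (data, [x], np.array([[yv]]), bu, np.array([bi]))
        kw = dict(a=a, lam=lam)
        assert abs(grad_x_u(*args, **kw)[0]) < 1e-3
        assert abs(grad_y_i(*args[:5], 0, **kw)[0]) < 1e-3
        assert abs(grad_beta_u(*args, **kw)) < 1e-3
        assert abs(grad_beta_i(*args[:5], 0, **kw)) < 1e-3


class TestFit:
    def test_separable_two_gene_problem(self):
        # With a large confidence weight the lone positive's optimum
        # probability a/(1+a) exceeds 0.95 and the negative's tends to 0.
        mf = LogisticMF(
            n_factors=1, a=40.0, lam=0.0, iterations=500,
            y_init="random", init_seed=3,
        ).fit(None, [1.0, 0.0])
        p = mf.predict_proba()
        assert p[0] > 0.95 and p[0] == pytest.approx(40 / 41, abs=0.01)
        assert p[1] < 0.05

    def test_same_seed_bit_identical(self, rng):
        X = rng.standard_normal((10, 4))
        r = rng.integers(0, 2, 10).astype(float)
        kw = dict(n_factors=3, iterations=50, init_seed=7)
        m1 = LogisticMF(**kw).fit(X, r)
        m2 = LogisticMF(**kw).fit(X, r)
        assert np.array_equal(m1.x_u_, m2.x_u_)
        assert np.array_equal(m1.Y_, m2.Y_)
        assert np.array_equal(m1.posterior_trace_, m2.posterior_trace_)

    def test_penalty_dominated_limit(self):
        mf = LogisticMF(
            n_factors=2, a=0.0, lam=1e3, iterations=3000,
            y_init="random", init_seed=1,
        ).fit(None, [1.0, 0.0, 1.0])
        assert np.linalg.norm(mf.x_u_) < 1e-2
        assert np.linalg.norm(mf.Y_) < 1e-2
        assert np.allclose(mf.predict_proba(), expit(mf.beta_u_ + mf.beta_), atol=1e-4)

    def test_posterior_trace_is_recorded_and_improves(self, rng):
        X = rng.standard_normal((15, 4))
        r = rng.integers(0, 2, 15).astype(float)
        mf = LogisticMF(n_factors=2, iterations=80, init_seed=0).fit(X, r)
        assert mf.posterior_trace_.shape == (81,)
        assert mf.posterior_trace_[-1] > mf.posterior_trace_[0]

    def test_trace_nondecreasing_after_burn_in(self):
        rng = np.random.default_rng(42)
        for i in range(8):
            n = int(rng.integers(2, 21))
            f = int(rng.integers(1, 5))
            r = rng.integers(0, 2, n).astype(float)
            mf = LogisticMF(
                n_factors=f, a=float(rng.uniform(0, 4)), lam=float(rng.uniform(0, 2)),
                iterations=120, learning_rate=0.05, y_init="random", init_seed=i,
            ).fit(None, r)
            assert np.diff(mf.posterior_trace_)[5:].min() >= -1e-8

    def test_gcn_init_requires_embeddings(self):
        with pytest.raises(ValueError, match="requires embeddings"):
            LogisticMF(y_init="gcn").fit(None, [1.0, 0.0])

    def test_gcn_init_needs_enough_columns(self, rng):
        with pytest.raises(ValueError, match="n_factors"):
            LogisticMF(n_factors=5).fit(rng.standard_normal((4, 2)), np.zeros(4))

    def test_masked_rows_stay_at_initialization(self, rng):
        X = rng.standard_normal((8, 3))
        r = np.array([1.0, 0, 0, 1, 0, 0, 0, 0])
        mask = np.array([True] * 4 + [False] * 4)
        mf = LogisticMF(n_factors=3, iterations=60, init_seed=0).fit(X, r, mask)
        mu, sd = X.mean(0), X.std(0)
        init = (X - mu) / np.where(sd > 0, sd, 1.0)
        assert np.array_equal(mf.Y_[4:], init[4:])
        assert not np.allclose(mf.Y_[:4], init[:4])
        assert np.all(mf.beta_[4:] == 0)

    def test_label_flip_symmetry(self, rng):
        # negating one factor side together with both biases negates every
        # linear score z, so probabilities map to their complements
        mf = LogisticMF(n_factors=3, iterations=30, init_seed=0).fit(
            rng.standard_normal((9, 3)), rng.integers(0, 2, 9).astype(float)
        )
        flipped = LogisticMF(n_factors=3)
        flipped.x_u_ = -mf.x_u_
        flipped.Y_ = mf.Y_
        flipped.beta_u_ = -mf.beta_u_
        flipped.beta_ = -mf.beta_
        flipped.n_genes_ = mf.n_genes_
        assert np.allclose(flipped.predict_proba(), 1 - mf.predict_proba(), atol=1e-12)


class TestPredictAndRank:
    @pytest.fixture
    def fitted(self, rng):
        X = rng.standard_normal((6, 3))
        r = np.array([1.0, 1, 0, 0, 0, 0])
        return LogisticMF(n_factors=3, iterations=60, init_seed=0).fit(X, r)

    def test_untrained_model_rejected(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            LogisticMF().predict_proba()

    def test_index_alignment(self, fitted):
        fwd = fitted.predict_proba([1, 4])
        rev = fitted.predict_proba([4, 1])
        assert np.array_equal(fwd, rev[::-1])

    def test_consistent_with_scalar_probability(self, fitted):
        probs = fitted.predict_proba()
        for i in range(fitted.n_genes_):
            assert probs[i] == pytest.approx(
                association_probability(
                    fitted.x_u_, fitted.Y_[i], fitted.beta_u_, fitted.beta_[i]
                )
            )

    def test_all_zero_model_predicts_half(self):
        mf = LogisticMF(n_factors=2)
        mf.x_u_, mf.Y_ = np.zeros(2), np.zeros((3, 2))
        mf.beta_u_, mf.beta_ = 0.0, np.zeros(3)
        mf.n_genes_ = 3
        assert np.all(mf.predict_proba() == 0.5)

    def test_rank_genes_sorted_and_excludable(self, fitted):
        genes = [f"G{i}" for i in range(6)]
        ranking = rank_genes(fitted, genes)
        probs = [p for _, p in ranking]
        assert probs == sorted(probs, reverse=True)
        assert rank_genes(fitted, genes, exclude=set(genes)) == []
        top = rank_genes(fitted, genes, exclude={"G0"})
        assert all(g != "G0" for g, _ in top)

    def test_tie_break_is_lexicographic(self):
        mf = LogisticMF(n_factors=1)
        mf.x_u_ = np.zeros(1)
        mf.Y_ = np.zeros((3, 1))
        mf.beta_u_, mf.beta_ = 0.0, np.zeros(3)
        mf.n_genes_ = 3
        assert [g for g, _ in rank_genes(mf, ["B", "C", "A"])] == ["A", "B", "C"]


class TestSerialization:
    def test_round_trip_is_exact(self, tmp_path, rng):
        X = rng.standard_normal((7, 3))
        r = rng.integers(0, 2, 7).astype(float)
        mf = LogisticMF(n_factors=3, iterations=40, init_seed=5).fit(X, r)
        genes = [f"G{i}" for i in range(7)]
        path = tmp_path / "model.json"
        save_model(path, genes, mf)
        genes2, mf2 = load_model(path)
        assert genes2 == genes
        assert np.array_equal(mf.x_u_, mf2.x_u_)
        assert np.array_equal(mf.Y_, mf2.Y_)
        assert mf.beta_u_ == mf2.beta_u_
        assert np.array_equal(mf.beta_, mf2.beta_)
        assert np.array_equal(mf.posterior_trace_, mf2.posterior_trace_)
        assert mf2.get_params() == mf.get_params()


class TestAssociationData:
    def test_rejects_negative_r(self):
        with pytest.raises(ValueError, match="non-negative"):
            AssociationData([-1.0])

    def test_rejects_mask_length_mismatch(self):
        with pytest.raises(ValueError, match="mask"):
            AssociationData([1.0, 0.0], mask=[True])
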