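"""The BiGRU + self-attention network against independent oracles."""

import math

import numpy as np
import pytest
from scipy.special import expit

from bgattgr.network import (
    AttentionParams,
    BGATTClassifier,
    GruParams,
    bigru_forward,
    extract_embeddings,
    gru_step,
    self_attention,
)


def scalar_gru_oracle(f, h, uz, wz, bz, ur, wr, br, uc, wc, bc):
    """Hand-evaluated scalar GRU recurrence (plain Python floats)."""
    sig = lambda x: 1.0 / (1.0 + math.exp(-x))
    z = sig(uz * f + wz * h + bz)
    r = sig(ur * f + wr * h + br)
    c = math.tanh(uc * f + r * (wc * h) + bc)
    return (1.0 - z) * c + z * h


def loop_gru_oracle(f, h, p: GruParams):
    """Element-by-element loop evaluation of the GRU equations."""
    d_h, d_in = p.U_z.shape
    out = np.empty(d_h)
    for i in range(d_h):
        az = p.b_z[i] + sum(p.U_z[i, j] * f[j] for j in range(d_in)) + sum(
            p.W_z[i, j] * h[j] for j in range(d_h)
        )
        ar = p.b_r[i] + sum(p.U_r[i, j] * f[j] for j in range(d_in)) + sum(
            p.W_r[i, j] * h[j] for j in range(d_h)
        )
        wch = sum(p.W_c[i, j] * h[j] for j in range(d_h))
        z = 1.0 / (1.0 + math.exp(-az))
        r = 1.0 / (1.0 + math.exp(-ar))
        ac = p.b_c[i] + sum(p.U_c[i, j] * f[j] for j in range(d_in)) + r * wch
        c = math.tanh(ac)
        out[i] = (1.0 - z) * c + z * h[i]
    return out


def random_params(rng, d_in, d_h, scale=1.0):
    g = lambda *s: rng.normal(scale=scale, size=s)
    return GruParams(
        U_z=g(d_h, d_in), U_r=g(d_h, d_in), U_c=g(d_h, d_in),
        W_z=g(d_h, d_h), W_r=g(d_h, d_h), W_c=g(d_h, d_h),
        b_z=g(d_h), b_r=g(d_h), b_c=g(d_h),
    )


class TestGruStep:
    def test_zero_params_halve_previous_state(self, rng):
        p = GruParams.zeros(3, 4)
        h = rng.normal(size=4)
        np.testing.assert_allclose(gru_step(rng.normal(size=3), h, p), 0.5 * h, atol=1e-12)

    def test_saturated_update_gate_copies_state(self, rng):
        p = GruParams.zeros(2, 3)
        p.b_z[:] = 20.0
        h = rng.normal(size=3)
        np.testing.assert_allclose(gru_step(rng.normal(size=2), h, p), h, atol=1e-6)

    def test_scalar_unit_weights_hand_value(self):
        ones = np.ones((1, 1))
        p = GruParams(
            U_z=ones, U_r=ones, U_c=ones,
            W_z=ones.copy(), W_r=ones.copy(), W_c=ones.copy(),
            b_z=np.zeros(1), b_r=np.zeros(1), b_c=np.zeros(1),
        )
        h = gru_step(np.array([1.0]), np.array([0.0]), p)
        # z = r = sigmoid(1), c = tanh(1), h = (1-z)*c
        expected = (1 - expit(1.0)) * math.tanh(1.0)
        assert h[0] == pytest.approx(expected, abs=1e-12)
        assert h[0] == pytest.approx(0.20482, abs=1e-5)

    @pytest.mark.parametrize("d_in,d_h", [(1, 1), (2, 3), (4, 4), (3, 2)])
    def test_agrees_with_loop_oracle(self, d_in, d_h, rng):
        for _ in range(5):
            p = random_params(rng, d_in, d_h)
            f, h = rng.normal(size=d_in), rng.normal(size=d_h)
            np.testing.assert_allclose(gru_step(f, h, p), loop_gru_oracle(f, h, p), atol=1e-10)

    def test_state_is_convex_combination(self, rng):
        """h_t lies elementwise between c_t and h_{t-1} (gates in (0,1))."""
        p = random_params(rng, 3, 5, scale=2.0)
        f, h = rng.normal(size=3), rng.normal(size=5)
        h_t = gru_step(f, h, p)
        # reconstruct the candidate to bound h_t
        z = expit(p.U_z @ f + p.W_z @ h + p.b_z)
        r = expit(p.U_r @ f + p.W_r @ h + p.b_r)
        c = np.tanh(p.U_c @ f + r * (p.W_c @ h) + p.b_c)
        assert ((z > 0) & (z < 1)).all() and ((r > 0) & (r < 1)).all()
        lo, hi = np.minimum(c, h), np.maximum(c, h)
        assert ((h_t >= lo - 1e-12) & (h_t <= hi + 1e-12)).all()

    def test_shape_mismatch_rejected(self):
        p = GruParams.zeros(2, 3)
        with pytest.raises(ValueError):
            gru_step(np.zeros(5), np.zeros(3), p)


class TestBigru:
    def test_single_token_width(self, rng):
        fwd, bwd = random_params(rng, 2, 3), random_params(rng, 2, 3)
        out = bigru_forward([rng.normal(size=2)], fwd, bwd)
        assert len(out) == 1 and out[0].shape == (6,)

    def test_empty_sequence_rejected(self, rng):
        p = random_params(rng, 2, 2)
        with pytest.raises(ValueError):
            bigru_forward([], p, p)

    def test_all_zero_params_give_zero_outputs(self):
        p = GruParams.zeros(2, 3)
        out = bigru_forward([np.ones(2)] * 4, p, p)
        for h in out:
            np.testing.assert_array_equal(h, np.zeros(6))

    def test_palindrome_symmetry(self, rng):
        """On a palindromic sequence with shared direction parameters, the
        output at position t equals the output at position d+1-t with the
        forward/backward halves swapped."""
        p = random_params(rng, 1, 1)
        a, b = rng.normal(size=1), rng.normal(size=1)
        seq = [a, b, a]
        out = bigru_forward(seq, p, p)
        d_h = 1
        for t in range(3):
            mirrored = out[2 - t]
            np.testing.assert_allclose(out[t][:d_h], mirrored[d_h:], atol=1e-12)
            np.testing.assert_allclose(out[t][d_h:], mirrored[:d_h], atol=1e-12)


class TestSelfAttention:
    def test_single_position_returns_its_value(self, rng):
        params = AttentionParams(
            W_q=rng.normal(size=(2, 3)), W_k=rng.normal(size=(2, 3)), W_v=rng.normal(size=(4, 3))
        )
        H = rng.normal(size=(1, 3))
        out, w = self_attention(H, params, return_weights=True)
        assert w == pytest.approx(1.0)
        np.testing.assert_allclose(out, H @ params.W_v.T, atol=1e-12)

    def test_identical_positions_get_uniform_weights(self, rng):
        params = AttentionParams(
            W_q=rng.normal(size=(2, 3)), W_k=rng.normal(size=(2, 3)), W_v=rng.normal(size=(3, 3))
        )
        H = np.tile(rng.normal(size=(1, 3)), (5, 1))
        out, w = self_attention(H, params, return_weights=True)
        np.testing.assert_allclose(w, np.full((5, 5), 0.2), atol=1e-12)
        np.testing.assert_allclose(out, H @ params.W_v.T, atol=1e-12)

    def test_two_position_hand_example(self):
        """1-D identity projections, H=[1,2]: first output row is
        softmax([1,2]) . [1,2] = 0.2689*1 + 0.7311*2."""
        eye = np.eye(1)
        params = AttentionParams(W_q=eye, W_k=eye, W_v=eye)
        H = np.array([[1.0], [2.0]])
        out, w = self_attention(H, params, return_weights=True)
        e1, e2 = math.exp(1.0), math.exp(2.0)
        w11 = e1 / (e1 + e2)
        assert w[0, 0] == pytest.approx(w11, abs=1e-12)
        assert w[0, 0] == pytest.approx(0.2689, abs=1e-4)
        assert out[0, 0] == pytest.approx(w11 * 1 + (1 - w11) * 2, abs=1e-12)
        assert out[0, 0] == pytest.approx(1.7311, abs=1e-4)

    def test_weight_rows_sum_to_one(self, rng):
        params = AttentionParams(
            W_q=rng.normal(size=(3, 4)), W_k=rng.normal(size=(3, 4)), W_v=rng.normal(size=(4, 4))
        )
        _, w = self_attention(rng.normal(size=(6, 4)), params, return_weights=True)
        np.testing.assert_allclose(w.sum(axis=1), np.ones(6), atol=1e-9)


def separable_data(rng, n=120, width=30):
    X = rng.normal(size=(n, width))
    y = (X[:, :5].sum(axis=1) > 0).astype(int)
    X[:, :5] += 2.0 * (2 * y[:, None] - 1)
    return X, y


class TestClassifier:
    def small(self, **kw):
        defaults = dict(n_tokens=5, d_model=16, d_h=16, attn_dim=8, epochs=25, random_state=2)
        defaults.update(kw)
        return BGATTClassifier(**defaults)

    def test_learns_separable_data(self, rng):
        X, y = separable_data(rng)
        clf = self.small().fit(X, y)
        from sklearn.metrics import balanced_accuracy_score

        assert balanced_accuracy_score(y, clf.predict(X)) >= 0.95

    def test_zero_epochs_keeps_seeded_initialization(self, rng):
        X, y = separable_data(rng, n=30)
        a = self.small(epochs=0).fit(X, y)
        b = self.small(epochs=0).fit(X, y)
        for key in a.params_:
            np.testing.assert_array_equal(a.params_[key], b.params_[key])
        assert a.loss_curve_ == []

    def test_fit_deterministic_under_seed(self, rng):
        X, y = separable_data(rng, n=60)
        a = self.small(epochs=5).fit(X, y)
        b = self.small(epochs=5).fit(X, y)
        for key in a.params_:
            np.testing.assert_array_equal(a.params_[key], b.params_[key])

    def test_gradients_match_finite_differences(self, rng):
        X = rng.normal(size=(10, 12))
        y = rng.integers(0, 2, size=10)
        clf = self.small(n_tokens=3, d_model=4, d_h=4, attn_dim=3, epochs=0).fit(X, y)
        y01 = (y == clf.classes_[1]).astype(float)

        def loss():
            probs, _ = clf._forward(X)
            pc = np.clip(probs, 1e-12, 1 - 1e-12)
            return -np.mean(y01 * np.log(pc) + (1 - y01) * np.log(1 - pc))

        _, _, cache = clf._forward(X, need_cache=True)
        grads = clf._backward(y01, cache)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for key, P in clf.params_.items():
            for _ in range(3):
                idx = tuple(check_rng.integers(0, s) for s in P.shape)
                orig = P[idx]
                P[idx] = orig + eps
                lp = loss()
                P[idx] = orig - eps
                lm = loss()
                P[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(numeric, rel=1e-3, abs=1e-7), key

    def test_embedding_width_is_twice_hidden(self, rng):
        X, y = separable_data(rng, n=40)
        clf = self.small(epochs=1).fit(X, y)
        E = clf.transform(X)
        assert E.shape == (40, 32)
        assert np.isfinite(E).all()

    def test_embeddings_deterministic_and_row_consistent(self, rng):
        X, y = separable_data(rng, n=30)
        clf = self.small(epochs=2).fit(X, y)
        E1, E2 = clf.transform(X), clf.transform(X)
        np.testing.assert_array_equal(E1, E2)
        X_dup = np.vstack([X[0], X[0]])
        E = clf.transform(X_dup)
        np.testing.assert_array_equal(E[0], E[1])

    def test_empty_input_transforms_to_zero_rows(self, rng):
        X, y = separable_data(rng, n=30)
        clf = self.small(epochs=1).fit(X, y)
        assert clf.transform(np.empty((0, X.shape[1]))).shape == (0, 32)
        assert extract_embeddings(clf, np.empty((0, X.shape[1]))).shape == (0, 32)

    def test_width_mismatch_rejected(self, rng):
        X, y = separable_data(rng, n=30)
        clf = self.small(epochs=1).fit(X, y)
        with pytest.raises(ValueError, match="width"):
            clf.transform(np.zeros((2, X.shape[1] + 1)))
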