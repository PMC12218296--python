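"""BiGRU with self-attention (the BGATT architecture), in pure NumPy.

Each compound's fused fingerprint vector is read as a short sequence of
tokens, one per descriptor view (or fixed-size chunks), each linearly
projected to a common model width.  A bidirectional GRU encodes the
sequence, scaled dot-product self-attention re-weights the per-token
states, and mean-pooling over tokens yields the compound embedding of
width ``2 * d_h`` (4000 under the default ``d_h = 2000``).  A sigmoid head
on the embedding trains the whole stack end-to-end on binary cross-entropy
by gradient descent (Adam), with gradients derived by hand.

The GRU cell uses an update gate ``z`` and a reset gate ``r``::

    z_t = sigmoid(U_z f_t + W_z h_{t-1} + b_z)
    r_t = sigmoid(U_r f_t + W_r h_{t-1} + b_r)
    c_t = tanh(U_c f_t + r_t * (W_c h_{t-1}) + b_c)
    h_t = (1 - z_t) * c_t + z_t * h_{t-1}

so ``h_t`` is elementwise a convex combination of the candidate state and
the previous state.  Attention is ``softmax(Q K^T / sqrt(d)) V`` with
``Q = H W_q``, ``K = H W_k``, ``V = H W_v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit as _sigmoid
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "GruParams",
    "AttentionParams",
    "gru_step",
    "bigru_forward",
    "self_attention",
    "BGATTClassifier",
    "train_bgatt",
    "extract_embeddings",
]


# ---------------------------------------------------------------------------
# Parameter containers and functional single-sequence ops (the reference API)

@dataclass
class GruParams:
    """One GRU direction: input maps U_*, recurrent maps W_*, biases b_*.

    ``U_*`` have shape ``(d_h, d_in)``, ``W_*`` shape ``(d_h, d_h)`` and
    ``b_*`` shape ``(d_h,)``.
    """

    U_z: np.ndarray
    U_r: np.ndarray
    U_c: np.ndarray
    W_z: np.ndarray
    W_r: np.ndarray
    W_c: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        d_h, d_in = self.U_z.shape
        for name in ("U_z", "U_r", "U_c"):
            if getattr(self, name).shape != (d_h, d_in):
                raise ValueError(f"{name} must have shape {(d_h, d_in)}")
        for name in ("W_z", "W_r", "W_c"):
            if getattr(self, name).shape != (d_h, d_h):
                raise ValueError(f"{name} must have shape {(d_h, d_h)}")
        for name in ("b_z", "b_r", "b_c"):
            if getattr(self, name).shape != (d_h,):
                raise ValueError(f"{name} must have shape {(d_h,)}")
        for name in ("U_z", "U_r", "U_c", "W_z", "W_r", "W_c", "b_z", "b_r", "b_c"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} contains non-finite values")

    @property
    def d_h(self) -> int:
        return self.U_z.shape[0]

    @property
    def d_in(self) -> int:
        return self.U_z.shape[1]

    @classmethod
    def zeros(cls, d_in: int, d_h: int) -> "GruParams":
        z = lambda *s: np.zeros(s)
        return cls(
            U_z=z(d_h, d_in), U_r=z(d_h, d_in), U_c=z(d_h, d_in),
            W_z=z(d_h, d_h), W_r=z(d_h, d_h), W_c=z(d_h, d_h),
            b_z=z(d_h), b_r=z(d_h), b_c=z(d_h),
        )


@dataclass
class AttentionParams:
    """Projection matrices for scaled dot-product self-attention.

    ``W_q`` and ``W_k`` map the input width to the attention dimensionality
    ``d`` (rows); the softmax logits are scaled by ``sqrt(d)``.
    """

    W_q: np.ndarray
    W_k: np.ndarray
    W_v: np.ndarray

    def __post_init__(self) -> None:
        if self.W_q.shape != self.W_k.shape:
            raise ValueError("W_q and W_k must share a shape")
        if self.W_v.shape[1] != self.W_q.shape[1]:
            raise ValueError("W_v must act on the same input width as W_q")
        if self.d <= 0:
            raise ValueError("attention dimensionality must be positive")

    @property
    def d(self) -> int:
        return self.W_q.shape[0]


def gru_step(f_t: np.ndarray, h_prev: np.ndarray, params: GruParams) -> np.ndarray:
    """One GRU cell update for a single input vector.

    Returns ``h_t = (1 - z) * c + z * h_prev`` with the gates defined in the
    module docstring.  Numerically stable through the logistic sigmoid.
    """
    f_t = np.asarray(f_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if f_t.shape != (params.d_in,):
        raise ValueError(f"f_t must have shape {(params.d_in,)}, got {f_t.shape}")
    if h_prev.shape != (params.d_h,):
        raise ValueError(f"h_prev must have shape {(params.d_h,)}, got {h_prev.shape}")
    z = _sigmoid(params.U_z @ f_t + params.W_z @ h_prev + params.b_z)
    r = _sigmoid(params.U_r @ f_t + params.W_r @ h_prev + params.b_r)
    c = np.tanh(params.U_c @ f_t + r * (params.W_c @ h_prev) + params.b_c)
    return (1.0 - z) * c + z * h_prev


def bigru_forward(
    sequence: Sequence[np.ndarray], fwd: GruParams, bwd: GruParams
) -> list[np.ndarray]:
    """Run both GRU directions over a token sequence from zero initial states.

    Position ``t`` of the output concatenates the forward state after
    consuming tokens ``1..t`` with the backward state after consuming tokens
    ``d..t``; each output vector has width ``2 * d_h``.
    """
    if len(sequence) == 0:
        raise ValueError("sequence must be non-empty")
    h = np.zeros(fwd.d_h)
    forward_states = []
    for f_t in sequence:
        h = gru_step(f_t, h, fwd)
        forward_states.append(h)
    g = np.zeros(bwd.d_h)
    backward_states: list[np.ndarray] = []
    for f_t in reversed(sequence):
        g = gru_step(f_t, g, bwd)
        backward_states.append(g)
    backward_states.reverse()
    return [np.concatenate([hf, hb]) for hf, hb in zip(forward_states, backward_states)]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def self_attention(
    H: np.ndarray | Sequence[np.ndarray],
    params: AttentionParams,
    return_weights: bool = False,
):
    """Scaled dot-product self-attention over one sequence of states.

    ``output = softmax(Q K^T / sqrt(d)) V`` with row-wise softmax, where
    ``Q = H W_q^T`` etc. for ``H`` of shape ``(T, width)``.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[0] == 0:
        raise ValueError("attention input must be non-empty")
    Q = H @ params.W_q.T
    K = H @ params.W_k.T
    V = H @ params.W_v.T
    weights = softmax(Q @ K.T / np.sqrt(params.d), axis=-1)
    out = weights @ V
    if return_weights:
        return out, weights
    return out


# ---------------------------------------------------------------------------
# Batched forward/backward used for training

def _gru_forward_batch(tokens: list[np.ndarray], p: dict, prefix: str):
    """Forward one GRU direction over tokens in processing order.

    ``tokens[t]`` has shape (n, d_model).  Returns the hidden states per
    step and the cache needed for backprop.
    """
    n = tokens[0].shape[0]
    d_h = p[f"{prefix}_b_z"].shape[0]
    h = np.zeros((n, d_h))
    states, cache = [], []
    for f in tokens:
        z = _sigmoid(f @ p[f"{prefix}_U_z"].T + h @ p[f"{prefix}_W_z"].T + p[f"{prefix}_b_z"])
        r = _sigmoid(f @ p[f"{prefix}_U_r"].T + h @ p[f"{prefix}_W_r"].T + p[f"{prefix}_b_r"])
        wch = h @ p[f"{prefix}_W_c"].T
        c = np.tanh(f @ p[f"{prefix}_U_c"].T + r * wch + p[f"{prefix}_b_c"])
        h_new = (1.0 - z) * c + z * h
        cache.append((f, h, z, r, c, wch))
        states.append(h_new)
        h = h_new
    return states, cache


def _gru_backward_batch(d_states: list[np.ndarray], cache, p: dict, prefix: str, grads: dict):
    """Backprop one GRU direction; returns d(token) per step (processing order)."""
    d_tokens = [None] * len(cache)
    dh_next = np.zeros_like(d_states[-1])
    for t in range(len(cache) - 1, -1, -1):
        f, h_prev, z, r, c, wch = cache[t]
        dh = d_states[t] + dh_next
        dz = dh * (h_prev - c)
        dc = dh * (1.0 - z)
        dh_prev = dh * z
        da_c = dc * (1.0 - c * c)
        dr = da_c * wch
        d_wch = da_c * r
        grads[f"{prefix}_U_c"] += da_c.T @ f
        grads[f"{prefix}_W_c"] += d_wch.T @ h_prev
        grads[f"{prefix}_b_c"] += da_c.sum(axis=0)
        dh_prev = dh_prev + d_wch @ p[f"{prefix}_W_c"]
        df = da_c @ p[f"{prefix}_U_c"]
        da_r = dr * r * (1.0 - r)
        grads[f"{prefix}_U_r"] += da_r.T @ f
        grads[f"{prefix}_W_r"] += da_r.T @ h_prev
        grads[f"{prefix}_b_r"] += da_r.sum(axis=0)
        dh_prev = dh_prev + da_r @ p[f"{prefix}_W_r"]
        df = df + da_r @ p[f"{prefix}_U_r"]
        da_z = dz * z * (1.0 - z)
        grads[f"{prefix}_U_z"] += da_z.T @ f
        grads[f"{prefix}_W_z"] += da_z.T @ h_prev
        grads[f"{prefix}_b_z"] += da_z.sum(axis=0)
        dh_prev = dh_prev + da_z @ p[f"{prefix}_W_z"]
        df = df + da_z @ p[f"{prefix}_U_z"]
        d_tokens[t] = df
        dh_next = dh_prev
    return d_tokens


class BGATTClassifier(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Binary classifier and embedding network over fused fingerprint vectors.

    ``fit`` trains projection matrices, a bidirectional GRU, self-attention
    and a sigmoid head end-to-end on binary cross-entropy; ``transform``
    returns the ``2 * d_h``-wide compound embeddings (the attention output
    mean-pooled over tokens, without the head).

    Parameters
    ----------
    view_offsets : mapping name -> (start, end), optional
        Half-open column ranges of the descriptor views inside the input
        matrix; one token per view.  When omitted, the input is cut into
        ``n_tokens`` near-equal chunks (or chunks of ``chunk_size`` columns
        if given).
    d_model : int
        Width each token is projected to before the recurrence.
    d_h : int
        Hidden width per GRU direction; the embedding width is ``2 * d_h``
        (the default 2000 gives the canonical 4000-wide embedding).
    attn_dim : int
        Dimensionality of the attention queries/keys (scaling ``sqrt(d)``).
    learning_rate, epochs, batch_size : training protocol (Adam).
    patience : int
        Early stopping after this many epochs without training-loss
        improvement; set to ``epochs`` to disable.
    random_state : int
        Seed for initialization and batch shuffling; fits are deterministic.
    """

    def __init__(
        self,
        view_offsets: Mapping[str, tuple[int, int]] | None = None,
        n_tokens: int = 5,
        chunk_size: int | None = None,
        d_model: int = 512,
        d_h: int = 2000,
        attn_dim: int = 64,
        learning_rate: float = 1e-3,
        epochs: int = 50,
        batch_size: int = 32,
        patience: int = 10,
        tol: float = 1e-5,
        random_state: int = 0,
    ):
        self.view_offsets = view_offsets
        self.n_tokens = n_tokens
        self.chunk_size = chunk_size
        self.d_model = d_model
        self.d_h = d_h
        self.attn_dim = attn_dim
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.tol = tol
        self.random_state = random_state

    # -- token layout -------------------------------------------------------
    def _resolve_offsets(self, width: int) -> list[tuple[int, int]]:
        if self.view_offsets is not None:
            offsets = sorted(self.view_offsets.values())
            if offsets[-1][1] != width:
                raise ValueError(
                    f"view_offsets cover width {offsets[-1][1]} but input has {width} columns"
                )
            return offsets
        if self.chunk_size is not None:
            edges = list(range(0, width, self.chunk_size)) + [width]
        else:
            cuts = np.linspace(0, width, self.n_tokens + 1).astype(int)
            edges = cuts.tolist()
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1) if edges[i + 1] > edges[i]]

    # -- initialization -----------------------------------------------------
    def _init_params(self, offsets, rng) -> dict:
        def glorot(*shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-limit, limit, size=shape)

        def orthogonal(n):
            a = rng.normal(size=(n, n))
            q, r = np.linalg.qr(a)
            return q * np.sign(np.diag(r))

        p: dict[str, np.ndarray] = {}
        for i, (s, e) in enumerate(offsets):
            p[f"P_{i}"] = glorot(e - s, self.d_model)
        for prefix in ("fwd", "bwd"):
            for gate in ("z", "r", "c"):
                p[f"{prefix}_U_{gate}"] = glorot(self.d_h, self.d_model)
                p[f"{prefix}_W_{gate}"] = orthogonal(self.d_h)
                p[f"{prefix}_b_{gate}"] = np.zeros(self.d_h)
        D = 2 * self.d_h
        p["W_q"] = glorot(self.attn_dim, D)
        p["W_k"] = glorot(self.attn_dim, D)
        p["W_v"] = glorot(D, D)
        p["head_w"] = glorot(D, 1)[:, 0]
        p["head_b"] = np.zeros(1)
        return p

    # -- forward ------------------------------------------------------------
    def _forward(self, X: np.ndarray, need_cache: bool = False):
        p = self.params_
        offsets = self.offsets_
        tokens = [X[:, s:e] @ p[f"P_{i}"] for i, (s, e) in enumerate(offsets)]
        fwd_states, fwd_cache = _gru_forward_batch(tokens, p, "fwd")
        bwd_states, bwd_cache = _gru_forward_batch(tokens[::-1], p, "bwd")
        bwd_states = bwd_states[::-1]
        H = np.stack(
            [np.concatenate([hf, hb], axis=1) for hf, hb in zip(fwd_states, bwd_states)],
            axis=1,
        )  # (n, T, 2*d_h)
        Q = H @ p["W_q"].T
        K = H @ p["W_k"].T
        V = H @ p["W_v"].T
        scale = np.sqrt(self.attn_dim)
        A = softmax(Q @ K.transpose(0, 2, 1) / scale, axis=-1)
        O = A @ V
        E = O.mean(axis=1)  # (n, 2*d_h)
        logits = E @ p["head_w"] + p["head_b"][0]
        probs = _sigmoid(logits)
        if not need_cache:
            return probs, E
        cache = dict(
            X=X, tokens=tokens, fwd_cache=fwd_cache, bwd_cache=bwd_cache,
            H=H, Q=Q, K=K, V=V, A=A, E=E, probs=probs, scale=scale,
        )
        return probs, E, cache

    def _backward(self, y01: np.ndarray, cache) -> dict:
        p = self.params_
        n, T, D = cache["H"].shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = (cache["probs"] - y01) / n
        grads["head_w"] += cache["E"].T @ dlogits
        grads["head_b"] += np.array([dlogits.sum()])
        dE = np.outer(dlogits, p["head_w"])
        dO = np.repeat(dE[:, None, :] / T, T, axis=1)
        A, Q, K, V, H = cache["A"], cache["Q"], cache["K"], cache["V"], cache["H"]
        dA = dO @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ dO
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = dS @ K / cache["scale"]
        dK = dS.transpose(0, 2, 1) @ Q / cache["scale"]
        grads["W_q"] += np.einsum("ntd,nte->de", dQ, H)
        grads["W_k"] += np.einsum("ntd,nte->de", dK, H)
        grads["W_v"] += np.einsum("ntd,nte->de", dV, H)
        dH = dQ @ p["W_q"] + dK @ p["W_k"] + dV @ p["W_v"]
        d_h = D // 2
        d_fwd = [dH[:, t, :d_h] for t in range(T)]
        d_bwd = [dH[:, t, d_h:] for t in range(T)]
        d_tok_f = _gru_backward_batch(d_fwd, cache["fwd_cache"], p, "fwd", grads)
        d_tok_b = _gru_backward_batch(d_bwd[::-1], cache["bwd_cache"], p, "bwd", grads)
        d_tok_b = d_tok_b[::-1]
        for i, (s, e) in enumerate(self.offsets_):
            d_token = d_tok_f[i] + d_tok_b[i]
            grads[f"P_{i}"] += cache["X"][:, s:e].T @ d_token
        return grads

    # -- sklearn API --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "BGATTClassifier":
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"binary classification only; got classes {self.classes_}")
        y01 = (y == self.classes_[1]).astype(float)
        self.offsets_ = self._resolve_offsets(X.shape[1])
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        self.params_ = self._init_params(self.offsets_, rng)
        self.embedding_width_ = 2 * self.d_h

        m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        v = {k: np.zeros_like(val) for k, val in self.params_.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss, stale = np.inf, 0
        self.loss_curve_ = []
        n = X.shape[0]
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                probs, _, cache = self._forward(X[idx], need_cache=True)
                yb = y01[idx]
                pclip = np.clip(probs, 1e-12, 1 - 1e-12)
                loss = -np.mean(yb * np.log(pclip) + (1 - yb) * np.log(1 - pclip))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch {start // self.batch_size}; "
                        "reduce the learning rate"
                    )
                epoch_loss += loss * len(idx)
                grads = self._backward(yb, cache)
                step += 1
                for key in self.params_:
                    g = grads[key]
                    m[key] = beta1 * m[key] + (1 - beta1) * g
                    v[key] = beta2 * v[key] + (1 - beta2) * g * g
                    mhat = m[key] / (1 - beta1**step)
                    vhat = v[key] / (1 - beta2**step)
                    self.params_[key] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss /= n
            self.loss_curve_.append(float(epoch_loss))
            if epoch_loss < best_loss - self.tol:
                best_loss, stale = epoch_loss, 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.empty((0, 2))
        probs, _ = self._forward(X)
        return np.column_stack([1 - probs, probs])

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Return the ``n x (2*d_h)`` compound embeddings (no head, no updates)."""
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input width {X.shape[1]} does not match the fitted width {self.n_features_in_}"
            )
        if X.shape[0] == 0:
            return np.empty((0, self.embedding_width_))
        _, E = self._forward(X)
        return E


def train_bgatt(dataset, view_offsets=None, **config) -> BGATTClassifier:
    """Train a :class:`BGATTClassifier` on a :class:`~bgattgr.augmentation.BalancedDataset`."""
    model = BGATTClassifier(view_offsets=view_offsets, **config)
    return model.fit(dataset.features, dataset.labels)


def extract_embeddings(model: BGATTClassifier, features) -> np.ndarray:
    """Embeddings for a fitted model; inference only, deterministic."""
    matrix = getattr(features, "matrix", features)
    return model.transform(np.asarray(matrix, dtype=float))
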