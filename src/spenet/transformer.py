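"""Encoder-decoder transformer over disease node-set pairs.

One disease pair (A, B) is classified by feeding the per-node encodings of
A's member nodes to a transformer encoder and B's to a decoder. Attention
is *unmasked* everywhere (no causal mask — node sets have no order); only
padding positions are excluded. The decoder output is an interaction
matrix X (d_model x n_B, one column per B node); the head converts it to a
probability:

    s    = softmax(squared column-wise L2 norms of X)   (simplex over B nodes)
    y'   = X diag(s) summed over columns                (attention-weighted pool)
    logit = w . y' + b,   prob = sigmoid(logit)

trained with binary cross-entropy on the logits.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

NEG_INF = -1e9


@dataclass(frozen=True)
class ModelConfig:
    """Transformer hyperparameters.

    d_model must match the encoding width (72 for SPE = 64 node-embedding +
    8 GPE columns; 64 for NoPE/LPE) and be divisible by the head count.
    ff_dim defaults to 4 * d_model (the usual transformer ratio).
    """

    d_model: int = 72
    layers: int = 3
    heads: int = 8
    ff_dim: int | None = None
    dropout: float = 0.2
    lr: float = 1e-4
    batch_size: int = 20

    def __post_init__(self) -> None:
        if self.d_model % self.heads != 0:
            raise ValueError(
                f"d_model={self.d_model} not divisible by heads={self.heads}"
            )
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def ff(self) -> int:
        return self.ff_dim if self.ff_dim is not None else 4 * self.d_model

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ff_dim"] = self.ff
        return d


@dataclass(frozen=True)
class Prediction:
    """Single-pair output: logit, probability, and the column-score simplex."""

    logit: float
    prob: float
    score_vector: np.ndarray


# ---------------------------------------------------------------------------
# head operations (numpy; the exact formulas, used for both inference and
# verification — the training path reimplements them on the autodiff tape)
# ---------------------------------------------------------------------------


def column_scores(X: np.ndarray) -> np.ndarray:
    """Softmax over squared column-wise L2 norms of X (m x n) -> simplex (n,)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError(f"X must be m x n with n >= 1, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    sq = (X * X).sum(axis=0)
    sq = sq - sq.max()
    e = np.exp(sq)
    return e / e.sum()


def weighted_pool(X: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Row sums of X diag(s): y'_i = sum_j s_j X_ij -> (m,)."""
    X = np.asarray(X, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if X.shape[1] != s.shape[0]:
        raise ValueError(f"X has {X.shape[1]} columns but s has {s.shape[0]} entries")
    return X @ s


def predict(y_prime: np.ndarray, w: np.ndarray, b: float,
            score_vector: np.ndarray | None = None) -> Prediction:
    """Linear layer + sigmoid on the pooled vector."""
    w = np.asarray(w, dtype=np.float64).reshape(-1)
    y_prime = np.asarray(y_prime, dtype=np.float64).reshape(-1)
    if w.shape != y_prime.shape:
        raise ValueError(f"head weight shape {w.shape} != pooled shape {y_prime.shape}")
    logit = float(w @ y_prime + b)
    prob = float(1.0 / (1.0 + np.exp(-logit)))
    if score_vector is None:
        score_vector = np.array([1.0])
    return Prediction(logit=logit, prob=prob, score_vector=score_vector)


def bce_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy in the numerically stable logit form."""
    z = np.asarray(logits, dtype=np.float64).reshape(-1)
    y = np.asarray(labels, dtype=np.float64).reshape(-1)
    if z.shape != y.shape:
        raise ValueError("logits and labels must have the same length")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be in {0, 1}")
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(per.mean())


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class PairTransformer:
    """Encoder-decoder transformer for disease node-set pairs.

    Parameters are initialised from ``seed`` (Glorot-uniform); all forward
    randomness (dropout) comes from an explicit generator so that training
    is reproducible single-threaded. Computation runs in float32 by
    default; pass dtype=np.float64 for high-precision checks.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.seed = seed
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params: dict[str, Parameter] = {}
        d, f = cfg.d_model, cfg.ff
        for side, n_layers in (("enc", cfg.layers), ("dec", cfg.layers)):
            for layer in range(n_layers):
                pre = f"{side}{layer}"
                blocks = ["self"] if side == "enc" else ["self", "cross"]
                for blk in blocks:
                    for name in ("wq", "wk", "wv", "wo"):
                        self._add(rng, f"{pre}.{blk}.{name}", (d, d))
                    for name in ("bq", "bk", "bv", "bo"):
                        self._zeros(f"{pre}.{blk}.{name}", (d,))
                    self._ones(f"{pre}.{blk}.ln_g", (d,))
                    self._zeros(f"{pre}.{blk}.ln_b", (d,))
                self._add(rng, f"{pre}.ff.w1", (d, f))
                self._zeros(f"{pre}.ff.b1", (f,))
                self._add(rng, f"{pre}.ff.w2", (f, d))
                self._zeros(f"{pre}.ff.b2", (d,))
                self._ones(f"{pre}.ff.ln_g", (d,))
                self._zeros(f"{pre}.ff.ln_b", (d,))
        self._add(rng, "head.w", (d, 1))
        self._zeros("head.b", (1,))

    # -- parameter plumbing ------------------------------------------------

    def _add(self, rng, name: str, shape: tuple[int, int]) -> None:
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        self.params[name] = Parameter(
            rng.uniform(-limit, limit, size=shape).astype(self.dtype)
        )

    def _zeros(self, name: str, shape) -> None:
        self.params[name] = Parameter(np.zeros(shape, dtype=self.dtype))

    def _ones(self, name: str, shape) -> None:
        self.params[name] = Parameter(np.ones(shape, dtype=self.dtype))

    def parameters(self) -> list[Parameter]:
        return [self.params[k] for k in sorted(self.params)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=self.dtype)

    # -- forward -----------------------------------------------------------

    def _attn(self, prefix: str, x_q: Tensor, x_kv: Tensor, key_mask: np.ndarray,
              rng, training: bool) -> Tensor:
        cfg = self.cfg
        P = self.params
        bias = np.where(key_mask[:, None, None, :], 0.0, NEG_INF).astype(self.dtype)
        drop = None
        if training and cfg.dropout > 0.0:
            drop = ad.dropout_mask(
                (x_q.shape[0], cfg.heads, x_q.shape[1], x_kv.shape[1]),
                cfg.dropout, rng, self.dtype,
            )
        return ad.multi_head_attention(
            x_q, x_kv,
            P[f"{prefix}.wq"], P[f"{prefix}.bq"],
            P[f"{prefix}.wk"], P[f"{prefix}.bk"],
            P[f"{prefix}.wv"], P[f"{prefix}.bv"],
            P[f"{prefix}.wo"], P[f"{prefix}.bo"],
            heads=cfg.heads, key_bias=bias, drop_mask=drop,
        )

    def _drop_mask(self, shape, rng, training: bool):
        if not training or self.cfg.dropout <= 0.0:
            return None
        return ad.dropout_mask(shape, self.cfg.dropout, rng, self.dtype)

    def _block(self, prefix: str, x: Tensor, sub_out: Tensor, rng, training: bool) -> Tensor:
        P = self.params
        mask = self._drop_mask(sub_out.shape, rng, training)
        return ad.residual_layer_norm(
            x, sub_out, P[f"{prefix}.ln_g"], P[f"{prefix}.ln_b"], drop_mask=mask
        )

    def _ff(self, prefix: str, x: Tensor, rng, training: bool) -> Tensor:
        P = self.params
        out = ad.feed_forward(
            x, P[f"{prefix}.w1"], P[f"{prefix}.b1"],
            P[f"{prefix}.w2"], P[f"{prefix}.b2"],
        )
        mask = self._drop_mask(out.shape, rng, training)
        return ad.residual_layer_norm(
            x, out, P[f"{prefix}.ln_g"], P[f"{prefix}.ln_b"], drop_mask=mask
        )

    def forward(
        self,
        enc_tokens: np.ndarray,
        dec_tokens: np.ndarray,
        enc_mask: np.ndarray,
        dec_mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Batched forward pass.

        enc_tokens: (B, nA, d_model); dec_tokens: (B, nB, d_model); masks
        are boolean with True marking real (unpadded) tokens. Returns
        (logits (B,), decoder outputs (B, nB, d_model)).
        """
        cfg = self.cfg
        if enc_tokens.shape[-1] != cfg.d_model or dec_tokens.shape[-1] != cfg.d_model:
            raise ValueError(
                f"token width {enc_tokens.shape[-1]}/{dec_tokens.shape[-1]} "
                f"!= d_model {cfg.d_model}"
            )
        if rng is None:
            rng = np.random.default_rng(0)
        enc_tokens = np.ascontiguousarray(enc_tokens, dtype=self.dtype)
        dec_tokens = np.ascontiguousarray(dec_tokens, dtype=self.dtype)
        x = Tensor(enc_tokens)
        for layer in range(cfg.layers):
            pre = f"enc{layer}"
            x = self._block(f"{pre}.self", x,
                            self._attn(f"{pre}.self", x, x, enc_mask, rng, training),
                            rng, training)
            x = self._ff(f"{pre}.ff", x, rng, training)
        memory = x
        y = Tensor(dec_tokens)
        for layer in range(cfg.layers):
            pre = f"dec{layer}"
            y = self._block(f"{pre}.self", y,
                            self._attn(f"{pre}.self", y, y, dec_mask, rng, training),
                            rng, training)
            y = self._block(f"{pre}.cross", y,
                            self._attn(f"{pre}.cross", y, memory, enc_mask, rng, training),
                            rng, training)
            y = self._ff(f"{pre}.ff", y, rng, training)

        # head on the tape: masked softmax over squared token norms
        sq = (y * y).sum(axis=-1)  # (B, nB)
        mask_bias = np.where(dec_mask, 0.0, NEG_INF).astype(self.dtype)
        s = ad.softmax(sq + Tensor(mask_bias), axis=-1)  # pads underflow to exactly 0
        pooled = (s.reshape(s.shape[0], s.shape[1], 1) * y).sum(axis=1)  # (B, d)
        logits = ad.linear(pooled, self.params["head.w"], self.params["head.b"]).reshape(-1)
        return logits, y

    # -- spec-level single/batch inference ---------------------------------

    def encode_decode(self, pairs: list[tuple[np.ndarray, np.ndarray]],
                      seed: int = 0) -> list[np.ndarray]:
        """Interaction matrices X (d_model x n_B) for a list of token-matrix
        pairs, inference mode (dropout off), padded internally."""
        enc, dec, me, md = pad_batch([p[0] for p in pairs], [p[1] for p in pairs])
        _, y = self.forward(enc, dec, me, md, training=False,
                            rng=np.random.default_rng(seed))
        out = []
        for i, (_, b_tokens) in enumerate(pairs):
            nb = b_tokens.shape[0]
            out.append(y.data[i, :nb, :].T.copy())
        return out

    def forward_pair(self, a_tokens: np.ndarray, b_tokens: np.ndarray,
                     seed: int = 0) -> Prediction:
        """encode_decode -> column_scores -> weighted_pool -> predict for one pair."""
        if a_tokens.shape[0] == 0 or b_tokens.shape[0] == 0:
            raise ValueError("both diseases need at least one member node")
        X = self.encode_decode([(a_tokens, b_tokens)], seed=seed)[0]
        s = column_scores(X)
        y_prime = weighted_pool(X, s)
        return predict(
            y_prime, self.params["head.w"].data, float(self.params["head.b"].data[0]),
            score_vector=s,
        )

    def predict_proba(self, pairs: list[tuple[np.ndarray, np.ndarray]],
                      batch_size: int = 64) -> np.ndarray:
        """Probabilities for many pairs (inference mode, size-sorted batches)."""
        order = np.argsort([a.shape[0] + b.shape[0] for a, b in pairs], kind="stable")
        probs = np.empty(len(pairs))
        rng = np.random.default_rng(0)
        for ofs in range(0, len(pairs), batch_size):
            idx = order[ofs : ofs + batch_size]
            chunk = [pairs[i] for i in idx]
            enc, dec, me, md = pad_batch([p[0] for p in chunk], [p[1] for p in chunk])
            logits, _ = self.forward(enc, dec, me, md, training=False, rng=rng)
            probs[idx] = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
        return probs


def pad_batch(a_list: list[np.ndarray], b_list: list[np.ndarray]):
    """Zero-pad variable-size token matrices into batch tensors + masks."""
    if len(a_list) != len(b_list) or not a_list:
        raise ValueError("need equal, nonzero numbers of A and B token matrices")
    d = a_list[0].shape[1]
    na = max(a.shape[0] for a in a_list)
    nb = max(b.shape[0] for b in b_list)
    B = len(a_list)
    enc = np.zeros((B, na, d))
    dec = np.zeros((B, nb, d))
    mask_e = np.zeros((B, na), dtype=bool)
    mask_d = np.zeros((B, nb), dtype=bool)
    for i, (a, b) in enumerate(zip(a_list, b_list)):
        if a.shape[0] == 0 or b.shape[0] == 0:
            raise ValueError(f"pair {i}: empty node set")
        enc[i, : a.shape[0]] = a
        dec[i, : b.shape[0]] = b
        mask_e[i, : a.shape[0]] = True
        mask_d[i, : b.shape[0]] = True
    return enc, dec, mask_e, mask_d
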