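"""Node embeddings via biased random walks and skip-gram with negative sampling.

The walk generator follows the node2vec transition rule: from current node
``v`` reached from ``t``, the unnormalized weight of stepping to candidate
``x`` is ``1/p`` if ``x == t`` (return), ``1`` if ``x`` is adjacent to
``t`` (stay local), and ``1/q`` otherwise (move outward). With the neutral
setting ``p = q = 1`` the walk is a plain uniform random walk, which is the
default here.

Walks are fed to a skip-gram model with negative sampling (SGNS), trained
with vectorised minibatch SGD and a linearly decaying learning rate. Both
stages are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .graph_data import Interactome


@dataclass(frozen=True)
class WalkConfig:
    """Walk and skip-gram hyperparameters.

    p, q are the node2vec return / in-out parameters; both default to 1
    (neutral walk). window=2 keeps the skip-gram context local; dim=64 is
    the node-embedding width. Walk length/count and epochs are recorded here
    so every run is auditable.
    """

    p: float = 1.0
    q: float = 1.0
    walk_length: int = 30
    walks_per_node: int = 10
    window: int = 2
    dim: int = 64
    epochs: int = 5
    negatives: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        for name in ("walk_length", "walks_per_node", "window", "dim", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_walks(g: Interactome, cfg: WalkConfig) -> list[list[int]]:
    """Biased second-order random walks, `walks_per_node` starting per node.

    A walk stops early at a node with no neighbors (isolated start nodes
    yield length-1 walks). Reproducible from cfg.seed.
    """
    if g.n_nodes == 0:
        raise ValueError("graph has no nodes")
    rng = np.random.default_rng(cfg.seed)
    nbrs = g.neighbors()
    nbr_sets = [set(a.tolist()) for a in nbrs]
    neutral = cfg.p == 1.0 and cfg.q == 1.0
    walks: list[list[int]] = []
    starts = np.repeat(np.arange(g.n_nodes), cfg.walks_per_node)
    for start in starts:
        walk = [int(start)]
        for _ in range(cfg.walk_length - 1):
            v = walk[-1]
            cand = nbrs[v]
            if cand.size == 0:
                break
            if neutral or len(walk) == 1:
                nxt = int(cand[rng.integers(cand.size)])
            else:
                t = walk[-2]
                w = np.empty(cand.size)
                for i, x in enumerate(cand):
                    if x == t:
                        w[i] = 1.0 / cfg.p
                    elif x in nbr_sets[t]:
                        w[i] = 1.0
                    else:
                        w[i] = 1.0 / cfg.q
                w /= w.sum()
                nxt = int(cand[rng.choice(cand.size, p=w)])
            walk.append(nxt)
        walks.append(walk)
    return walks


def walk_step_weights(
    g: Interactome, prev: int, current: int, cfg: WalkConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized next-step distribution from `current` given previous node.

    Exposed for verification: returns (candidate node indices, probabilities).
    """
    nbrs = g.neighbors()
    cand = nbrs[current]
    prev_set = set(nbrs[prev].tolist())
    w = np.empty(cand.size)
    for i, x in enumerate(cand):
        if x == prev:
            w[i] = 1.0 / cfg.p
        elif int(x) in prev_set:
            w[i] = 1.0
        else:
            w[i] = 1.0 / cfg.q
    return cand, w / w.sum()


def _skipgram_pairs(walks: list[list[int]], window: int) -> np.ndarray:
    pairs = []
    for walk in walks:
        L = len(walk)
        for i, center in enumerate(walk):
            lo = max(0, i - window)
            hi = min(L, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, walk[j]))
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def train_node_embeddings(
    walks: list[list[int]], cfg: WalkConfig, n_nodes: int | None = None
) -> np.ndarray:
    """Skip-gram with negative sampling over the walk corpus.

    Returns an ``N x dim`` float matrix aligned to the node index space.
    Negative contexts are drawn from the unigram distribution raised to
    0.75 (the standard SGNS smoothing); learning rate decays linearly from
    0.025. Deterministic given cfg.seed (single-threaded numpy).
    """
    if not walks:
        raise ValueError("no walks provided")
    if n_nodes is None:
        n_nodes = max(max(w) for w in walks) + 1
    counts = np.zeros(n_nodes, dtype=np.int64)
    for w in walks:
        for v in w:
            counts[v] += 1
    missing = np.nonzero(counts == 0)[0]
    if missing.size:
        raise ValueError(f"nodes missing from all walks: {missing.tolist()[:20]}")

    rng = np.random.default_rng(cfg.seed + 1)
    pairs = _skipgram_pairs(walks, cfg.window)
    noise = counts.astype(np.float64) ** 0.75
    noise /= noise.sum()

    dim = cfg.dim
    W_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    W_out = np.zeros((n_nodes, dim))

    lr0, lr_min = 0.025, 1e-4
    batch = 1024
    n_pairs = pairs.shape[0]
    total_steps = cfg.epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for ofs in range(0, n_pairs, batch):
            idx = order[ofs : ofs + batch]
            centers = pairs[idx, 0]
            contexts = pairs[idx, 1]
            b = centers.size
            negs = rng.choice(n_nodes, size=(b, cfg.negatives), p=noise)
            lr = max(lr_min, lr0 * (1.0 - step / max(total_steps, 1)))
            step += 1

            vi = W_in[centers]  # (b, dim)
            vo = W_out[contexts]  # (b, dim)
            vn = W_out[negs]  # (b, neg, dim)

            pos_score = 1.0 / (1.0 + np.exp(-np.clip(np.einsum("bd,bd->b", vi, vo), -30, 30)))
            neg_score = 1.0 / (1.0 + np.exp(-np.clip(np.einsum("bd,bnd->bn", vi, vn), -30, 30)))

            g_pos = (pos_score - 1.0)[:, None]  # d/dscore of -log sigma
            g_neg = neg_score[..., None]  # (b, neg, 1)

            grad_vi = g_pos * vo + np.einsum("bnk,bnd->bd", g_neg, vn)
            grad_vo = g_pos * vi
            grad_vn = g_neg * vi[:, None, :]

            np.add.at(W_in, centers, -lr * grad_vi)
            np.add.at(W_out, contexts, -lr * grad_vo)
            np.add.at(W_out, negs.ravel(), -lr * grad_vn.reshape(-1, dim))
    return W_in


def node2vec_embedding(g: Interactome, cfg: WalkConfig) -> np.ndarray:
    """Walks + SGNS in one call; matrix rows follow the interactome node order."""
    walks = generate_walks(g, cfg)
    return train_node_embeddings(walks, cfg, n_nodes=g.n_nodes)
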