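"""Pair transformer: head formulas, masking, invariances, trainability."""

import numpy as np
import pytest

from spenet import transformer as tf
from spenet.autodiff import Adam, bce_with_logits


class TestColumnScores:
    def test_symmetric_columns(self):
        s = tf.column_scores(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(s, [0.5, 0.5])

    def test_direct_softmax_evaluation(self):
        s = tf.column_scores(np.array([[2.0, 0.0], [0.0, 1.0]]))
        expect = np.exp([4.0, 1.0])
        expect /= expect.sum()
        assert np.allclose(s, expect)
        assert s[0] == pytest.approx(0.9526, abs=1e-4)

    def test_identical_columns_uniform(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 5))
        assert np.allclose(tf.column_scores(X), 0.2)

    def test_sums_to_one_and_errors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(6, int(rng.integers(1, 9))))
            assert tf.column_scores(X).sum() == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError):
            tf.column_scores(np.empty((3, 0)))


class TestWeightedPool:
    def test_uniform_weights(self):
        y = tf.weighted_pool(np.eye(2), np.array([0.5, 0.5]))
        assert np.allclose(y, [0.5, 0.5])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            X = rng.normal(size=(5, 4))
            s = tf.column_scores(X)
            y = tf.weighted_pool(X, s)
            loop = np.array([sum(s[j] * X[i, j] for j in range(4)) for i in range(5)])
            assert np.allclose(y, loop, atol=1e-12)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 5))
        perm = rng.permutation(5)
        y1 = tf.weighted_pool(X, tf.column_scores(X))
        y2 = tf.weighted_pool(X[:, perm], tf.column_scores(X[:, perm]))
        assert np.allclose(y1, y2, atol=1e-12)


class TestPredict:
    def test_zero_head_gives_half(self):
        p = tf.predict(np.ones(5), np.zeros(5), 0.0)
        assert p.prob == 0.5

    def test_sigmoid_limits(self):
        assert tf.predict(np.ones(1), np.array([50.0]), 0.0).prob > 1 - 1e-10
        assert tf.predict(np.ones(1), np.array([0.0]), 0.0).prob == 0.5

    def test_direct_evaluation(self):
        y = np.full(10, 0.1)
        p = tf.predict(y, np.ones(10), 0.0)
        assert p.logit == pytest.approx(1.0)
        assert p.prob == pytest.approx(0.7311, abs=1e-4)


class TestBceLoss:
    def test_ln2_at_zero_logit(self):
        assert tf.bce_loss([0.0], [1]) == pytest.approx(np.log(2))

    def test_saturation(self):
        assert tf.bce_loss([20.0], [1]) < 1e-8

    def test_mean_of_equal_terms(self):
        assert tf.bce_loss([0.0, 0.0], [1, 0]) == pytest.approx(np.log(2))

    def test_label_validation(self):
        with pytest.raises(ValueError):
            tf.bce_loss([0.1], [0.5])


@pytest.fixture(scope="module")
def small_model():
    return tf.PairTransformer(
        tf.ModelConfig(d_model=72, dropout=0.0, lr=1e-3), seed=7
    )


class TestForward:
    def test_interaction_matrix_shape(self, small_model):
        rng = np.random.default_rng(3)
        X = small_model.encode_decode([(rng.normal(size=(3, 72)), rng.normal(size=(2, 72)))])[0]
        assert X.shape == (72, 2)

    def test_determinism_same_seed(self, small_model):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(4, 72)), rng.normal(size=(3, 72))
        p1 = small_model.forward_pair(a, b)
        p2 = small_model.forward_pair(a, b)
        assert p1.logit == p2.logit

    def test_token_permutation_invariance(self, small_model):
        """Reordering A tokens or B tokens leaves the probability unchanged:
        no positional order is injected inside the transformer."""
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(6, 72)), rng.normal(size=(5, 72))
        base = small_model.forward_pair(a, b).prob
        for _ in range(3):
            pa, pb = rng.permutation(6), rng.permutation(5)
            assert small_model.forward_pair(a[pa], b[pb]).prob == pytest.approx(
                base, abs=1e-5
            )

    def test_padding_cannot_change_scores_or_pool(self, small_model):
        """A pair evaluated alone equals the same pair inside a padded batch."""
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(3, 72)), rng.normal(size=(2, 72))
        big_a, big_b = rng.normal(size=(10, 72)), rng.normal(size=(9, 72))
        solo = small_model.predict_proba([(a, b)])
        batched = small_model.predict_proba([(big_a, big_b), (a, b)])
        assert batched[1] == pytest.approx(solo[0], abs=1e-6)
        # and the padded columns carry exactly zero head weight
        enc, dec, me, md = tf.pad_batch([a, big_a], [b, big_b])
        logits, y = small_model.forward(enc, dec, me, md)
        sq = (y.data**2).sum(axis=-1)
        bias = np.where(md, 0.0, tf.NEG_INF)
        e = np.exp(sq + bias - (sq + bias).max(axis=-1, keepdims=True))
        s = e / e.sum(axis=-1, keepdims=True)
        assert (s[0, 2:] == 0).all()

    def test_zeroed_head_gives_half(self, small_model):
        rng = np.random.default_rng(7)
        saved = small_model.state_dict()
        small_model.params["head.w"].data[:] = 0
        small_model.params["head.b"].data[:] = 0
        p = small_model.forward_pair(rng.normal(size=(4, 72)), rng.normal(size=(3, 72)))
        small_model.load_state_dict(saved)
        assert p.prob == 0.5

    def test_pair_order_matters(self, small_model):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(4, 72)), rng.normal(size=(4, 72))
        # architecture is asymmetric in (A, B); document by example
        assert small_model.forward_pair(a, b).prob != pytest.approx(
            small_model.forward_pair(b, a).prob, abs=1e-12
        )

    def test_empty_disease_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.forward_pair(np.empty((0, 72)), np.ones((2, 72)))

    def test_d_model_mismatch(self, small_model):
        with pytest.raises(ValueError):
            small_model.forward_pair(np.ones((2, 10)), np.ones((2, 10)))


def test_head_gradient_finite_difference():
    """d(loss)/d(head weights) from the tape matches central differences."""
    cfg = tf.ModelConfig(d_model=16, layers=1, heads=4, dropout=0.0)
    m = tf.PairTransformer(cfg, seed=0, dtype=np.float64)
    rng = np.random.default_rng(9)
    enc, dec, me, md = tf.pad_batch([rng.normal(size=(3, 16))], [rng.normal(size=(2, 16))])
    y = np.array([1.0])

    def loss_val():
        logits, _ = m.forward(enc, dec, me, md)
        return bce_with_logits(logits, y).data.item()

    logits, _ = m.forward(enc, dec, me, md)
    loss = bce_with_logits(logits, y)
    loss.backward()
    w = m.params["head.w"]
    eps = 1e-6
    for idx in [(0, 0), (7, 0), (15, 0)]:
        auto = w.grad[idx]
        w.data[idx] += eps
        fp = loss_val()
        w.data[idx] -= 2 * eps
        fm = loss_val()
        w.data[idx] += eps
        fd = (fp - fm) / (2 * eps)
        assert auto == pytest.approx(fd, rel=1e-4, abs=1e-10)


def test_overfits_twenty_pairs():
    """Capacity check: 20 pairs to BCE < 0.05 within 500 steps."""
    for seed in range(2):
        rng = np.random.default_rng(seed)
        pairs = [
            (rng.normal(size=(int(rng.integers(3, 8)), 72)),
             rng.normal(size=(int(rng.integers(3, 8)), 72)))
            for _ in range(20)
        ]
        labels = rng.integers(0, 2, 20).astype(float)
        cfg = tf.ModelConfig(dropout=0.0, lr=1e-3)
        m = tf.PairTransformer(cfg, seed=seed)
        opt = Adam(m.parameters(), lr=cfg.lr)
        enc, dec, me, md = tf.pad_batch([p[0] for p in pairs], [p[1] for p in pairs])
        final = None
        for step in range(500):
            logits, _ = m.forward(enc, dec, me, md)
            loss = bce_with_logits(logits, labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            final = loss.data.item()
            if final < 0.05:
                break
        assert final < 0.05, f"seed {seed}: loss {final} after {step} steps"
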