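"""Prototype-pool construction, nearest-prototype classification and the
pull/push loss, each checked against exhaustive or hand-computed oracles."""

import numpy as np
import pytest

from mriproto.autodiff import Parameter, Tensor
from mriproto.nn import AdamW
from mriproto.pcm import (
    LossConfig,
    PrototypePool,
    build_prototype_pool,
    class_centers,
    classify,
    cosine_distance,
    prototype_loss,
)
from mriproto.synthetic_data import generate_embedding_clusters


class TestCosineDistance:
    def test_self_distance_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_distance_two(self):
        v = np.array([1.0, -2.0])
        assert cosine_distance(v, -v) == pytest.approx(2.0, abs=1e-12)

    def test_closed_form_45_degrees(self):
        d = cosine_distance(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        assert d == pytest.approx(1.0 - 1.0 / np.sqrt(2), abs=1e-12)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 5))
            d = cosine_distance(a, b)
            assert d == pytest.approx(cosine_distance(b, a))
            assert 0.0 <= d <= 2.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance(np.zeros(3), np.ones(3))


class TestClassCenters:
    def test_singleton_and_midpoint(self):
        feats = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        labels = np.array([0, 0, 1])
        centers = class_centers(feats, labels, 2)
        assert np.allclose(centers[0], [0.5, 0.5])
        assert np.allclose(centers[1], [2.0, 2.0])

    def test_matches_loop_sum_oracle(self, rng):
        feats = rng.normal(size=(20, 6))
        labels = np.zeros(20, dtype=int)
        acc = np.zeros(6)
        for f in feats:
            acc += f
        assert np.allclose(class_centers(feats, labels, 1)[0], acc / 20, atol=1e-12)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            class_centers(np.ones((2, 2)), np.zeros(2, dtype=int), 2)


class TestBuildPrototypePool:
    def test_forced_selection_when_class_size_equals_g(self):
        feats = np.array([[1.0, 0.0], [0.0, 1.0]])
        labels = np.array([0, 0])
        pool = build_prototype_pool(feats, labels, G=2, n_classes=1)
        assert len(pool.vectors) == 2
        assert {tuple(v) for v in pool.vectors} == {(1.0, 0.0), (0.0, 1.0)}

    def test_exhaustive_ranking_oracle(self):
        feats = np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0]])
        labels = np.zeros(3, dtype=int)
        center = feats.mean(axis=0)
        dists = [cosine_distance(f, center) for f in feats]
        keep = np.argsort(dists, kind="stable")[:2]
        pool = build_prototype_pool(feats, labels, G=2, n_classes=1)
        assert np.allclose(pool.vectors, feats[np.sort(keep)][np.argsort(np.argsort(keep))]) or {
            tuple(v) for v in pool.vectors
        } == {tuple(feats[i]) for i in keep}

    def test_g_larger_than_class_clamps(self):
        feats = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        labels = np.array([0, 0, 1])
        pool = build_prototype_pool(feats, labels, G=5, n_classes=2)
        assert np.sum(pool.class_ids == 0) == 2
        assert np.sum(pool.class_ids == 1) == 1

    def test_prototypes_are_verbatim_training_features(self, rng):
        feats = rng.normal(size=(30, 8))
        labels = rng.integers(0, 3, size=30)
        pool = build_prototype_pool(feats, labels, G=2, n_classes=3)
        rows = {tuple(f) for f in feats}
        for v in pool.vectors:
            assert tuple(v) in rows


class TestClassify:
    def test_exact_prototype_match(self, rng):
        feats = rng.normal(size=(12, 5))
        labels = np.repeat(np.arange(4), 3)
        pool = build_prototype_pool(feats, labels, G=2, n_classes=4)
        target = pool.vectors[pool.class_ids == 3][0]
        res = classify(target, pool)
        assert res.predicted == 3
        assert res.distances[3] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_prototype_order(self, rng):
        feats = rng.normal(size=(8, 4))
        labels = np.repeat(np.arange(2), 4)
        pool = build_prototype_pool(feats, labels, G=2, n_classes=2)
        q = rng.normal(size=4)
        res = classify(q, pool)
        perm = PrototypePool(
            vectors=pool.vectors[::-1].copy(),
            class_ids=pool.class_ids[::-1].copy(),
            G=pool.G,
            C=pool.C,
        )
        res2 = classify(q, perm)
        assert res.predicted == res2.predicted
        assert np.allclose(res.distances, res2.distances)

    def test_brute_force_over_all_prototypes(self, rng):
        for _ in range(30):
            feats = rng.normal(size=(8, 6))
            labels = np.repeat(np.arange(4), 2)
            pool = build_prototype_pool(feats, labels, G=2, n_classes=4)
            q = rng.normal(size=6)
            res = classify(q, pool)
            best_c, best_d = None, np.inf
            for vec, cid in zip(pool.vectors, pool.class_ids):
                d = cosine_distance(q, vec)
                if d < best_d - 1e-15 or (d < best_d + 1e-15 and (best_c is None or cid < best_c)):
                    best_c, best_d = int(cid), min(d, best_d)
            assert res.predicted == best_c
            assert np.all((res.distances >= 0) & (res.distances <= 2))


class TestPrototypeLoss:
    def _simple_pool(self):
        vectors = np.array([[1.0, 0.0], [0.0, 1.0]])
        return PrototypePool(vectors=vectors, class_ids=np.array([0, 1]), G=1, C=2)

    def test_zero_pull_at_prototype(self):
        pool = self._simple_pool()
        cfg = LossConfig(alpha=1.0, beta=0.0, ce_weight=0.0)
        loss = prototype_loss(Tensor(np.array([1.0, 0.0])), 0, pool, None, cfg)
        assert loss.data == pytest.approx(0.0, abs=1e-12)

    def test_uniform_logits_cross_entropy_is_log_c(self):
        pool = self._simple_pool()
        cfg = LossConfig(alpha=0.0, beta=0.0, ce_weight=1.0)
        logits = Tensor(np.zeros(2))
        loss = prototype_loss(Tensor(np.array([3.0, 4.0])), 1, pool, logits, cfg)
        assert loss.data == pytest.approx(np.log(2.0), abs=1e-12)

    def test_hand_computed_total(self):
        """C=2, G=1, width 2: all three terms recomputed with scalars."""
        pool = self._simple_pool()
        cls = np.array([0.6, 0.8])
        cfg = LossConfig(alpha=1.0, beta=0.05, ce_weight=1.0, temperature=1.0)
        d0 = 1.0 - 0.6  # cos to (1,0) of unit vector (0.6,0.8)
        d1 = 1.0 - 0.8
        pull = d0
        push = d1
        z = np.array([-d0, -d1])
        ce = np.log(np.exp(z).sum()) - z[0]
        expected = cfg.alpha * pull - cfg.beta * push + ce
        loss = prototype_loss(Tensor(cls), 0, pool, None, cfg)
        assert loss.data == pytest.approx(expected, abs=1e-10)

    def test_invalid_class_rejected(self):
        pool = self._simple_pool()
        with pytest.raises(ValueError):
            prototype_loss(Tensor(np.ones(2)), 5, pool, None, LossConfig())

    def test_finite_difference_gradient(self):
        pool = self._simple_pool()
        cfg = LossConfig(alpha=1.0, beta=0.0, ce_weight=0.0)
        x0 = np.array([0.3, 0.9])
        p = Parameter(x0.copy())
        prototype_loss(p, 0, pool, None, cfg).backward()
        eps = 1e-7
        num = np.zeros(2)
        for i in range(2):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            num[i] = (
                prototype_loss(Tensor(xp), 0, pool, None, cfg).data
                - prototype_loss(Tensor(xm), 0, pool, None, cfg).data
            ) / (2 * eps)
        assert np.allclose(p.grad, num, atol=1e-5)

    def test_gradient_step_decreases_pull_distance(self):
        pool = self._simple_pool()
        cfg = LossConfig(alpha=1.0, beta=0.0, ce_weight=0.0)
        p = Parameter(np.array([0.2, 1.0]))
        before = cosine_distance(p.data, pool.vectors[0])
        opt = AdamW([p], lr=0.01, weight_decay=0.0)
        loss = prototype_loss(p, 0, pool, None, cfg)
        opt.zero_grad()
        loss.backward()
        opt.step()
        after = cosine_distance(p.data, pool.vectors[0])
        assert after < before


def test_separated_clusters_classify_perfectly():
    feats, labels = generate_embedding_clusters(4, 10, 16, separation=np.pi / 2, seed=0, noise_sd=0.01)
    pool = build_prototype_pool(feats, labels, G=2, n_classes=4)
    preds = np.array([classify(f, pool).predicted for f in feats])
    assert np.mean(preds == labels) == 1.0
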