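"""Prototype Classification Module.

Instead of a parametric classification head, each class is represented by a
small pool of stored training-sample embeddings (prototypes): the G samples
whose CLS features lie closest, in cosine distance, to the class feature
center. A query is classified by the class whose nearest prototype has the
smallest cosine distance. Training pulls a sample toward its own class's
nearest prototype, pushes it away from other classes' nearest prototypes, and
adds a cross-entropy term:

    L = alpha * min_j d(CLS, p_{q,j})
        - beta * mean_{i != q} min_j d(CLS, p_{i,j})
        + ce_weight * CE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "PrototypePool",
    "ClassificationResult",
    "LossConfig",
    "cosine_distance",
    "class_centers",
    "build_prototype_pool",
    "classify",
    "prototype_loss",
]


@dataclass
class PrototypePool:
    """Stored prototype embeddings with their class assignments.

    ``vectors[j]`` is a verbatim copy of a training CLS feature; prototypes of
    class i are the rows where ``class_ids == i``. Each class contributes
    min(G, class sample count) prototypes.
    """

    vectors: np.ndarray  # (P, d)
    class_ids: np.ndarray  # (P,)
    G: int
    C: int

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.class_ids = np.asarray(self.class_ids, dtype=int)
        if self.vectors.ndim != 2 or len(self.class_ids) != len(self.vectors):
            raise ValueError("pool vectors and class_ids are inconsistent")
        for i in range(self.C):
            n = int(np.sum(self.class_ids == i))
            if n < 1 or n > self.G:
                raise ValueError(f"class {i} has {n} prototypes (G={self.G})")

    def class_vectors(self, i: int) -> np.ndarray:
        return self.vectors[self.class_ids == i]


@dataclass
class ClassificationResult:
    distances: np.ndarray  # (C,) per-class minimum cosine distance
    predicted: int

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=np.float64)


@dataclass
class LossConfig:
    alpha: float = 1.0
    beta: float = 0.05
    ce_weight: float = 1.0
    temperature: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _check_nonzero(v: np.ndarray, what: str) -> None:
    if np.linalg.norm(v) == 0:
        raise ValueError(f"{what} is a zero vector; cosine distance undefined")


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(a, b); symmetric, in [0, 2], zero iff positively collinear."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal width")
    _check_nonzero(a, "first argument")
    _check_nonzero(b, "second argument")
    sim = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(1.0 - np.clip(sim, -1.0, 1.0))


def class_centers(features: np.ndarray, labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class arithmetic mean of the feature vectors."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    centers = np.zeros((n_classes, features.shape[1]))
    for i in range(n_classes):
        mask = labels == i
        if not mask.any():
            raise ValueError(f"class {i} has no samples")
        centers[i] = features[mask].mean(axis=0)
    return centers


def build_prototype_pool(
    features: np.ndarray, labels: np.ndarray, G: int, n_classes: int | None = None
) -> PrototypePool:
    """Select, per class, the min(G, n_i) features nearest the class center.

    Ties in cosine distance break by sample order; the stored vectors are
    verbatim copies of the selected training features.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    C = int(labels.max()) + 1 if n_classes is None else n_classes
    centers = class_centers(features, labels, C)
    vectors: list[np.ndarray] = []
    ids: list[int] = []
    for i in range(C):
        idx = np.flatnonzero(labels == i)
        dists = np.array([cosine_distance(features[j], centers[i]) for j in idx])
        order = np.argsort(dists, kind="stable")[: min(G, len(idx))]
        for j in idx[order]:
            vectors.append(features[j].copy())
            ids.append(i)
    return PrototypePool(vectors=np.array(vectors), class_ids=np.array(ids), G=G, C=C)


def classify(cls: np.ndarray, pool: PrototypePool) -> ClassificationResult:
    """Nearest-prototype classification: DIS_i = min_j d(cls, p_{i,j});
    the prediction is argmin_i DIS_i (ties to the smallest class index)."""
    cls = np.asarray(cls, dtype=np.float64)
    _check_nonzero(cls, "query")
    distances = np.empty(pool.C)
    for i in range(pool.C):
        protos = pool.class_vectors(i)
        distances[i] = min(cosine_distance(cls, p) for p in protos)
    return ClassificationResult(distances=distances, predicted=int(np.argmin(distances)))


def _cosine_distances_t(cls: Tensor, protos: np.ndarray) -> Tensor:
    """Differentiable cosine distances from ``cls`` (d,) to each row of protos."""
    p_norms = np.linalg.norm(protos, axis=1)
    if np.any(p_norms == 0):
        raise ValueError("prototype pool contains a zero vector")
    cls_norm = (cls * cls).sum() ** 0.5
    dots = Tensor(protos) @ cls  # (P,)
    return 1.0 - dots / (cls_norm * Tensor(p_norms))


def per_class_min_distances(cls: Tensor, pool: PrototypePool) -> Tensor:
    """Differentiable (C,) vector of per-class nearest-prototype distances."""
    dists = _cosine_distances_t(cls, pool.vectors)
    mins = []
    for i in range(pool.C):
        idx = np.flatnonzero(pool.class_ids == i)
        mins.append(dists[idx].min_over(axis=0).reshape(1))
    return concat(mins, axis=0)


def prototype_loss(
    cls: Tensor,
    q: int,
    pool: PrototypePool,
    fc_logits: Tensor | None,
    cfg: LossConfig,
) -> Tensor:
    """Pull/push prototype loss plus cross-entropy (see module docstring).

    When ``fc_logits`` is None the cross-entropy uses distance-based logits
    softmax(-DIS_i / temperature), the classification rule the module actually
    applies once the FC head is removed.
    """
    if not (0 <= q < pool.C):
        raise ValueError(f"invalid class index {q}")
    dis = per_class_min_distances(cls, pool)  # (C,)
    pull = dis[q]
    if pool.C > 1:
        others = np.array([i for i in range(pool.C) if i != q])
        push = dis[others].mean()
    else:
        push = Tensor(0.0)
    logits = fc_logits if fc_logits is not None else dis * (-1.0 / cfg.temperature)
    shift = float(logits.data.max())
    log_z = ((logits - shift).exp().sum()).log() + shift
    ce = log_z - logits[q]
    return cfg.alpha * pull - cfg.beta * push + cfg.ce_weight * ce
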