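"""Two-stage training protocol, evaluation metrics and cross-validation.

Protocol: (1) pretrain the encoder with an FC + softmax head under
cross-entropy; (2) extract training CLS features from the pretrained model
and build the per-class prototype pool; (3) continue training under the
prototype pull/push loss with the pool held fixed; (4) evaluate by
nearest-prototype classification. The frozen backbone never updates in any
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .data_io import AugmentConfig, Manifest, Volume, augment, minmax_normalize, split_folds
from .model import ModelConfig, SequenceClassifier
from .nn import AdamW, cosine_warmup_lr
from .pcm import (
    LossConfig,
    PrototypePool,
    build_prototype_pool,
    classify,
    cosine_distance,
    prototype_loss,
)

__all__ = [
    "TrainConfig",
    "EvalReport",
    "pretrain",
    "train_prototype_stage",
    "extract_features",
    "evaluate",
    "run_protocol",
    "cross_validate",
    "aggregate_reports",
]


@dataclass
class TrainConfig:
    epochs: int = 26
    warmup_epochs: int = 2
    proto_epochs: int = 8
    batch_size: int = 8
    learning_rate: float = 3e-3
    proto_learning_rate: float = 1e-3
    weight_decay: float = 0.01
    seed: int = 0
    ablation_mode: str = "fsm_pcm"
    G: int = 2
    loss: LossConfig = field(default_factory=LossConfig)
    refresh_interval: int = 0  # rebuild the pool every E prototype epochs; 0 = frozen
    proto_ce: str = "fc"  # cross-entropy logits in the prototype stage: fc | distance

    def __post_init__(self):
        if self.warmup_epochs > self.epochs:
            raise ValueError("warmup_epochs must not exceed epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.ablation_mode not in ("base", "fsm", "fsm_pcm"):
            raise ValueError(f"unknown ablation_mode {self.ablation_mode!r}")
        if self.proto_ce not in ("fc", "distance"):
            raise ValueError(f"unknown proto_ce {self.proto_ce!r}")


def ablation_train_config(mode: str, seed: int) -> TrainConfig:
    """Training configuration for module-ablation comparisons.

    The prototype stage is full training in the source protocol, not a brief
    fine-tune, so here it receives the same epoch budget as pretraining; the
    quick default (short prototype stage) is meant for pipeline validation
    rather than module comparison.
    """
    return TrainConfig(seed=seed, ablation_mode=mode, proto_epochs=26)


@dataclass
class EvalReport:
    accuracy: float
    per_class_recall: list[float | None]
    per_class_precision: list[float | None]
    confusion: np.ndarray  # (C, C), rows = true class
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_recall": self.per_class_recall,
            "per_class_precision": self.per_class_precision,
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }


def _forward_mode(ablation_mode: str) -> str:
    """Network topology used for a given ablation configuration."""
    return "base" if ablation_mode == "base" else "fsm"


def _prepare_batch(
    volumes: list[Volume],
    idx: np.ndarray,
    aug: AugmentConfig,
    rng: np.random.Generator | None,
    train: bool,
) -> tuple[np.ndarray, np.ndarray]:
    arrs, labels = [], []
    for i in idx:
        v = augment(volumes[i], aug, rng=rng, train=train)
        arrs.append(minmax_normalize(v.intensities))
        labels.append(volumes[i].label)
    return np.stack(arrs), np.array(labels, dtype=int)


def _cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy over a batch; logits (B, C)."""
    b = logits.shape[0]
    shift = logits.data.max(axis=1, keepdims=True)
    log_z = ((logits - shift).exp().sum(axis=1)).log() + shift[:, 0]
    picked = logits[np.arange(b), targets]
    return (log_z - picked).mean()


def pretrain(
    volumes: list[Volume],
    model: SequenceClassifier,
    cfg: TrainConfig,
    aug: AugmentConfig,
) -> dict:
    """Stage 1: FC-head cross-entropy training. Returns the loss history."""
    if not volumes:
        raise ValueError("empty training set")
    mode = _forward_mode(cfg.ablation_mode)
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.trainable_parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = {"epoch_loss": [], "lr": []}
    n = len(volumes)
    for epoch in range(cfg.epochs):
        opt.lr = cosine_warmup_lr(epoch, cfg.epochs, cfg.warmup_epochs, cfg.learning_rate)
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            arr, labels = _prepare_batch(volumes, idx, aug, rng, train=True)
            out = model.forward_batch(arr, mode=mode, with_fc=True)
            loss = _cross_entropy(out.fc_logits, labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["epoch_loss"].append(float(np.mean(losses)))
        history["lr"].append(opt.lr)
    return history


def extract_features(
    volumes: list[Volume],
    model: SequenceClassifier,
    mode: str,
    aug: AugmentConfig,
    batch_size: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-mode CLS features (center crop, no stochastic augmentation)."""
    feats, labels = [], []
    with no_grad():
        for lo in range(0, len(volumes), batch_size):
            idx = np.arange(lo, min(lo + batch_size, len(volumes)))
            arr, labs = _prepare_batch(volumes, idx, aug, rng=None, train=False)
            out = model.forward_batch(arr, mode=mode, with_fc=False)
            feats.append(out.cls.data)
            labels.append(labs)
    return np.concatenate(feats), np.concatenate(labels)


def train_prototype_stage(
    volumes: list[Volume],
    model: SequenceClassifier,
    pool: PrototypePool,
    cfg: TrainConfig,
    aug: AugmentConfig,
) -> tuple[PrototypePool, dict]:
    """Stage 2: optimize the pull/push + CE loss with prototypes held fixed
    (optionally refreshed every ``refresh_interval`` epochs)."""
    if pool.vectors.shape[1] != model.cfg.encoder.width:
        raise ValueError("prototype pool width does not match the model")
    mode = _forward_mode(cfg.ablation_mode)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = AdamW(
        model.trainable_parameters(), lr=cfg.proto_learning_rate, weight_decay=cfg.weight_decay
    )
    history = {"epoch_loss": [], "epoch_pull": []}
    n = len(volumes)
    for epoch in range(cfg.proto_epochs):
        if cfg.refresh_interval and epoch > 0 and epoch % cfg.refresh_interval == 0:
            feats, labels = extract_features(volumes, model, mode, aug)
            pool = build_prototype_pool(feats, labels, cfg.G, model.cfg.n_classes)
        opt.lr = cosine_warmup_lr(epoch, cfg.proto_epochs, 0, cfg.proto_learning_rate)
        perm = rng.permutation(n)
        losses, pulls = [], []
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            arr, labels = _prepare_batch(volumes, idx, aug, rng, train=True)
            use_fc = cfg.proto_ce == "fc"
            out = model.forward_batch(arr, mode=mode, with_fc=use_fc)
            sample_losses = [
                prototype_loss(
                    out.cls[b, :],
                    int(q),
                    pool,
                    out.fc_logits[b, :] if use_fc else None,
                    cfg.loss,
                ).reshape(1)
                for b, q in enumerate(labels)
            ]
            loss = concat(sample_losses, axis=0).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            for b, q in enumerate(labels):
                protos = pool.class_vectors(int(q))
                cvec = out.cls.data[b]
                pulls.append(min(cosine_distance(cvec, p) for p in protos))
        history["epoch_loss"].append(float(np.mean(losses)))
        history["epoch_pull"].append(float(np.mean(pulls)))
    return pool, history


def _report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> EvalReport:
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t, p] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total)
    recalls: list[float | None] = []
    precisions: list[float | None] = []
    for i in range(n_classes):
        row = confusion[i].sum()
        col = confusion[:, i].sum()
        recalls.append(float(confusion[i, i] / row) if row else None)
        precisions.append(float(confusion[i, i] / col) if col else None)
    return EvalReport(
        accuracy=accuracy,
        per_class_recall=recalls,
        per_class_precision=precisions,
        confusion=confusion,
        n=int(total),
    )


def evaluate(
    model: SequenceClassifier,
    pool: PrototypePool | None,
    volumes: list[Volume],
    cfg: TrainConfig,
    aug: AugmentConfig,
) -> EvalReport:
    """Per-sample prediction: nearest prototype when a pool is given,
    otherwise the FC head's argmax (base / fsm ablation configurations)."""
    if not volumes:
        raise ValueError("empty test set")
    mode = _forward_mode(cfg.ablation_mode)
    y_true, y_pred = [], []
    with no_grad():
        for lo in range(0, len(volumes), cfg.batch_size):
            idx = np.arange(lo, min(lo + cfg.batch_size, len(volumes)))
            arr, labels = _prepare_batch(volumes, idx, aug, rng=None, train=False)
            out = model.forward_batch(arr, mode=mode, with_fc=pool is None)
            if pool is not None:
                preds = [classify(out.cls.data[b], pool).predicted for b in range(len(idx))]
            else:
                preds = list(np.argmax(out.fc_logits.data, axis=1))
            y_true.extend(labels.tolist())
            y_pred.extend(int(p) for p in preds)
    return _report_from_predictions(np.array(y_true), np.array(y_pred), model.cfg.n_classes)


def run_protocol(
    train_volumes: list[Volume],
    test_volumes: list[Volume],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    aug: AugmentConfig,
) -> tuple[EvalReport, SequenceClassifier, PrototypePool | None, dict]:
    """Full protocol for one split: pretrain -> (pool -> prototype stage) -> evaluate.

    For the ``base`` and ``fsm`` ablation configurations the prototype stage
    is skipped and the FC head classifies.
    """
    model = SequenceClassifier(model_cfg)
    model.build_for_shape(aug.crop_shape)
    histories: dict = {}
    histories["pretrain"] = pretrain(train_volumes, model, train_cfg, aug)
    pool = None
    if train_cfg.ablation_mode == "fsm_pcm":
        feats, labels = extract_features(train_volumes, model, "fsm", aug)
        pool = build_prototype_pool(feats, labels, train_cfg.G, model_cfg.n_classes)
        pool, histories["prototype"] = train_prototype_stage(
            train_volumes, model, pool, train_cfg, aug
        )
    report = evaluate(model, pool, test_volumes, train_cfg, aug)
    return report, model, pool, histories


def aggregate_reports(reports: list[EvalReport]) -> dict:
    accs = np.array([r.accuracy for r in reports])

    def macro(values_list):
        means = []
        for vals in values_list:
            defined = [v for v in vals if v is not None]
            means.append(float(np.mean(defined)) if defined else np.nan)
        return means

    recalls = macro([r.per_class_recall for r in reports])
    precisions = macro([r.per_class_precision for r in reports])
    return {
        "accuracy_mean": float(accs.mean()),
        "accuracy_sd": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        "macro_recall_mean": float(np.nanmean(recalls)),
        "macro_precision_mean": float(np.nanmean(precisions)),
        "fold_accuracies": accs.tolist(),
    }


def cross_validate(
    volumes: list[Volume],
    manifest: Manifest,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    aug: AugmentConfig,
    n_folds: int = 5,
) -> tuple[dict, list[EvalReport]]:
    """Patient-grouped k-fold cross-validation of the full protocol."""
    folds = split_folds(manifest, n_folds, seed=train_cfg.seed)
    reports = []
    for train_idx, test_idx in folds:
        report, *_ = run_protocol(
            [volumes[i] for i in train_idx],
            [volumes[i] for i in test_idx],
            model_cfg,
            train_cfg,
            aug,
        )
        reports.append(report)
    return aggregate_reports(reports), reports
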