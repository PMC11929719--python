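"""Transfer-learning harness: fine-tuning with a chosen augmentation,
attention-head selection, and the erasing-probability sweep.

A linear classification layer is added on top of the (pretrained) teacher
backbone's CLS feature and the entire network is fine-tuned with Adam using
one-vs-all sigmoid outputs and summed binary cross-entropy (prediction =
arg-max score; conventional softmax cross-entropy is available behind a
flag). Augmentations apply to training images only — validation and test
batches are always clean. Early stopping monitors validation macro F1.

Head selection treats each attention head as a hyperparameter: one training
run per head with erasing restricted to that head (shared seed), keeping the
head with the highest validation macro F1 (ties -> lowest index). The
probability sweep does the same over candidate erasing probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from ._autodiff import Adam, Tensor
from .augment import (BinaryMask, ErasingPolicy, REPolicy, ThresholdSpec,
                      apply_erasing, attention_to_mask, random_erasing)
from .phantoms import PhantomSample, SplitDataset
from .stats import macro_f1
from .vit import AttentionMapSet, VisionTransformer, extract_cls_attention

__all__ = [
    "TrainConfig",
    "RunResult",
    "HeadSelectionReport",
    "SweepReport",
    "AGEAugmentation",
    "train_classifier",
    "select_head",
    "sweep_probability",
    "teacher_attention_source",
]

AttentionSource = Callable[[PhantomSample], AttentionMapSet]


@dataclass(frozen=True)
class TrainConfig:
    """Fine-tuning hyperparameters.

    Defaults follow the reference protocol (100 epochs max, batch 8, Adam
    with learning rate 5e-6 and weight decay 1e-4, five repetitions); toy
    phantom runs override epochs/learning rate to suit random-initialized
    desk-scale backbones.
    """

    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 5e-6
    weight_decay: float = 1e-4
    patience: int = 10
    n_repeats: int = 5
    seed: int = 0
    use_softmax_ce: bool = False
    screening_epochs: int | None = None  # reduced budget for head/P selection
    freeze_backbone: bool = False  # linear-probe mode: train the head only
    clip_norm: float | None = 1.0  # global gradient-norm clip for stability

    def __post_init__(self):
        if self.epochs < 1 or self.patience < 1 or self.n_repeats < 1:
            raise ValueError("epochs, patience and n_repeats must be >= 1")


@dataclass
class RunResult:
    """Metrics of one fine-tuning run."""

    train_losses: list[float]
    val_f1s: list[float]
    best_val_f1: float
    best_epoch: int          # 1-based epoch of the best validation F1
    test_f1: float
    seed: int

    def __post_init__(self):
        if self.val_f1s:
            assert abs(self.best_val_f1 - max(self.val_f1s)) < 1e-12


@dataclass
class HeadSelectionReport:
    per_head_val_f1: list[float]
    selected_head: int       # 1-based
    tie_broken: bool

    def __post_init__(self):
        best = max(self.per_head_val_f1)
        assert self.per_head_val_f1[self.selected_head - 1] == best


@dataclass
class SweepReport:
    probabilities: list[float]
    per_p_val_f1: list[float]
    best_probability: float
    tie_broken: bool


@dataclass
class AGEAugmentation:
    """Attention-guided erasing bound to an attention source.

    ``attention_source`` maps a sample to its attention maps — either CLS
    attention extracted from a frozen pretrained teacher or a fixture
    provider. Masks are computed once per training image and cached; only
    the Bernoulli draw is repeated per epoch.
    """

    policy: ErasingPolicy
    attention_source: AttentionSource
    _mask_cache: dict[str, np.ndarray] = field(default_factory=dict)

    def pixel_mask(self, sample: PhantomSample) -> np.ndarray:
        key = sample.sample_id or str(id(sample))
        if key not in self._mask_cache:
            attention = self.attention_source(sample)
            patch_mask = attention_to_mask(attention.head(self.policy.head_index),
                                           self.policy.threshold)
            self._mask_cache[key] = patch_mask.upsample(
                sample.image.shape[0]).cells
        return self._mask_cache[key]

    def __call__(self, sample: PhantomSample, rng: np.random.Generator) -> np.ndarray:
        # P = 0 is the identity and consumes no randomness, so a P = 0 arm is
        # bit-identical to the no-erasing arm under a shared seed
        if self.policy.probability == 0.0:
            return sample.image.copy()
        if rng.random() >= self.policy.probability:
            return sample.image.copy()
        return apply_erasing(sample.image, BinaryMask(
            self.pixel_mask(sample), resolution_tag="pixel"),
            self.policy.fill_value)


def teacher_attention_source(backbone: VisionTransformer) -> AttentionSource:
    """Attention source reading final-layer CLS attention off a frozen teacher."""
    cache: dict[str, AttentionMapSet] = {}

    def source(sample: PhantomSample) -> AttentionMapSet:
        key = sample.sample_id or str(id(sample))
        if key not in cache:
            cache[key] = extract_cls_attention(backbone, sample.image)
        return cache[key]

    return source


class _Classifier:
    """Backbone + new linear classification layer, all trainable.

    The head reads the CLS feature concatenated with the mean patch-token
    feature; the pooled half keeps local lesion structure visible to the
    head while the backbone's CLS attention is still near-uniform.
    """

    def __init__(self, backbone: VisionTransformer, n_classes: int, seed: int):
        self.backbone = backbone.clone()
        self.backbone.set_trainable(True)
        rng = np.random.default_rng(seed)
        d = 2 * backbone.config.embed_dim
        self.head_w = Tensor(rng.normal(0, (1.0 / d) ** 0.5, (d, n_classes)),
                             requires_grad=True)
        self.head_b = Tensor(np.zeros(n_classes), requires_grad=True)
        self.n_classes = n_classes

    def parameters(self) -> dict[str, Tensor]:
        return {**self.backbone.params, "cls_head.w": self.head_w,
                "cls_head.b": self.head_b}

    def logits(self, images: np.ndarray) -> Tensor:
        feats = self.backbone.forward_pooled(images)
        return feats @ self.head_w + self.head_b

    def predict(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(images).data, axis=1)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, p in self.parameters().items():
            p.data = arrays[k].copy()


def _loss_from_logits(z: Tensor, labels: np.ndarray, n_classes: int,
                      use_softmax_ce: bool) -> Tensor:
    onehot = np.eye(n_classes)[labels]
    if use_softmax_ce:
        return -(Tensor(onehot) * z.log_softmax(axis=-1)).sum(axis=-1).mean()
    # one-vs-all sigmoid BCE summed over classes:
    # BCE(z, y) = softplus(z) - y*z  (per class, numerically stable)
    return (z.softplus() - Tensor(onehot) * z).sum(axis=-1).mean()


def _loss(model: _Classifier, images: np.ndarray, labels: np.ndarray,
          use_softmax_ce: bool) -> Tensor:
    return _loss_from_logits(model.logits(images), labels, model.n_classes,
                             use_softmax_ce)


def _evaluate(model: _Classifier, samples: list[PhantomSample],
              batch_size: int) -> float:
    labels, preds = [], []
    for lo in range(0, len(samples), batch_size):
        chunk = samples[lo:lo + batch_size]
        imgs = np.stack([s.image for s in chunk])
        preds.extend(model.predict(imgs))
        labels.extend(s.label for s in chunk)
    return macro_f1(labels, preds, model.n_classes)


def train_classifier(backbone: VisionTransformer, dataset: SplitDataset,
                     augmentation: AGEAugmentation | REPolicy | None,
                     config: TrainConfig, seed: int,
                     max_epochs: int | None = None) -> RunResult:
    """Fine-tune the backbone + classification layer under one augmentation arm.

    Training images pass through the augmentation (fresh Bernoulli draw per
    image per epoch); validation and test stay clean. Stops once validation
    macro F1 has not improved for ``patience`` epochs and reports the metrics
    of the best-validation-epoch model.
    """
    train = dataset.split("train")
    val = dataset.split("val")
    test = dataset.split("test")
    if not train or not val:
        raise ValueError("train and validation splits must be nonempty")
    if dataset.n_classes < 2:
        raise ValueError("need at least 2 classes")
    epochs = max_epochs if max_epochs is not None else config.epochs
    rng = np.random.default_rng(seed)
    model = _Classifier(backbone, dataset.n_classes, seed)
    if config.freeze_backbone:
        model.backbone.set_trainable(False)
        params = {"cls_head.w": model.head_w, "cls_head.b": model.head_b}
    else:
        params = model.parameters()
    opt = Adam(params, lr=config.learning_rate,
               weight_decay=config.weight_decay, clip_norm=config.clip_norm)
    # with a frozen backbone the features of each (image, erased/clean) state
    # are constant across epochs, so they are computed once and the per-epoch
    # work reduces to the linear head
    feat_cache: dict[tuple[int, bool], np.ndarray] = {}

    def features(i: int, image: np.ndarray, augmented: bool) -> np.ndarray:
        key = (i, augmented)
        if key not in feat_cache:
            feat_cache[key] = model.backbone.forward_pooled(image[None]).data[0]
        return feat_cache[key]

    def train_image(i: int) -> tuple[np.ndarray, bool]:
        s = train[i]
        if augmentation is None:
            return s.image, False
        if isinstance(augmentation, REPolicy):
            return random_erasing(s.image, augmentation, rng), True
        if augmentation.policy.probability == 0.0:
            return s.image, False
        if rng.random() >= augmentation.policy.probability:
            return s.image, False
        return apply_erasing(s.image, BinaryMask(
            augmentation.pixel_mask(s), resolution_tag="pixel"),
            augmentation.policy.fill_value), True

    eval_cache: dict[str, float] = {}

    def eval_split(samples: list[PhantomSample], name: str) -> float:
        if not config.freeze_backbone:
            return _evaluate(model, samples, config.batch_size)
        key = name  # frozen backbone: clean-split features never change
        if key not in eval_cache:
            feats = np.stack([model.backbone.forward_pooled(
                s.image[None]).data[0] for s in samples])
            eval_cache[key] = feats  # type: ignore[assignment]
        feats = eval_cache[key]
        z = feats @ model.head_w.data + model.head_b.data
        preds = np.argmax(z, axis=1)
        return macro_f1([s.label for s in samples], preds, model.n_classes)

    best_f1, best_epoch, since_best = -1.0, 0, 0
    best_state: dict[str, np.ndarray] | None = None
    train_losses: list[float] = []
    val_f1s: list[float] = []
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(train))
        losses = []
        for lo in range(0, len(train), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            labels = np.array([train[i].label for i in idx])
            if config.freeze_backbone:
                feats = []
                for i in idx:
                    img, augmented = train_image(i)
                    if augmented and isinstance(augmentation, REPolicy):
                        feats.append(model.backbone.forward_pooled(
                            img[None]).data[0])
                    else:
                        feats.append(features(i, img, augmented))
                z = Tensor(np.stack(feats)) @ model.head_w + model.head_b
                loss = _loss_from_logits(z, labels, model.n_classes,
                                         config.use_softmax_ce)
            else:
                batch = np.stack([train_image(i)[0] for i in idx])
                loss = _loss(model, batch, labels, config.use_softmax_ce)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        train_losses.append(float(np.mean(losses)))
        vf1 = eval_split(val, "val")
        val_f1s.append(vf1)
        if vf1 > best_f1:
            best_f1, best_epoch, since_best = vf1, epoch, 0
            best_state = model.state_arrays()
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    assert best_state is not None
    model.load_state_arrays(best_state)
    test_f1 = eval_split(test, "test") if test else float("nan")
    return RunResult(train_losses=train_losses, val_f1s=val_f1s,
                     best_val_f1=best_f1, best_epoch=best_epoch,
                     test_f1=test_f1, seed=seed)


def select_head(backbone: VisionTransformer, dataset: SplitDataset,
                threshold: ThresholdSpec, probability: float,
                config: TrainConfig,
                attention_source: AttentionSource | None = None,
                fill_value: float = 0.0) -> HeadSelectionReport:
    """One AGE training run per attention head (shared seed); keep the arg-max.

    ``attention_source`` defaults to CLS attention extracted from the frozen
    ``backbone`` itself; a fixture provider can be injected for testing.
    """
    n_heads = backbone.config.n_heads
    source = attention_source or teacher_attention_source(backbone)
    budget = config.screening_epochs
    per_head: list[float] = []
    for head in range(1, n_heads + 1):
        policy = ErasingPolicy(head_index=head, threshold=threshold,
                               probability=probability, fill_value=fill_value)
        aug = AGEAugmentation(policy=policy, attention_source=source)
        try:
            result = train_classifier(backbone, dataset, aug, config,
                                      seed=config.seed, max_epochs=budget)
        except Exception as exc:
            raise RuntimeError(f"training failed for attention head {head}") from exc
        per_head.append(result.best_val_f1)
    best = max(per_head)
    selected = per_head.index(best) + 1
    tie = per_head.count(best) > 1
    return HeadSelectionReport(per_head_val_f1=per_head, selected_head=selected,
                               tie_broken=tie)


def sweep_probability(backbone: VisionTransformer, dataset: SplitDataset,
                      augmentation_family: str, probabilities: list[float],
                      config: TrainConfig,
                      threshold: ThresholdSpec | None = None,
                      head_index: int = 1,
                      attention_source: AttentionSource | None = None,
                      re_policy: REPolicy | None = None) -> SweepReport:
    """One selection run per candidate probability P; arg-max with lowest-P ties."""
    if not probabilities:
        raise ValueError("probability list must be nonempty")
    if any(not 0.0 <= p <= 1.0 for p in probabilities):
        raise ValueError("probabilities must lie in [0, 1]")
    if augmentation_family not in ("RE", "AGE"):
        raise ValueError("augmentation_family must be 'RE' or 'AGE'")
    budget = config.screening_epochs
    per_p: list[float] = []
    for p in probabilities:
        if augmentation_family == "RE":
            base = re_policy or REPolicy()
            aug: AGEAugmentation | REPolicy | None = replace(base, probability=p)
        else:
            source = attention_source or teacher_attention_source(backbone)
            policy = ErasingPolicy(head_index=head_index,
                                   threshold=threshold or ThresholdSpec(),
                                   probability=p)
            aug = AGEAugmentation(policy=policy, attention_source=source)
        result = train_classifier(backbone, dataset, aug, config,
                                  seed=config.seed, max_epochs=budget)
        per_p.append(result.best_val_f1)
    best = max(per_p)
    idx = per_p.index(best)
    return SweepReport(probabilities=list(probabilities), per_p_val_f1=per_p,
                       best_probability=float(probabilities[idx]),
                       tie_broken=per_p.count(best) > 1)
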