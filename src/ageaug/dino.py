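"""Teacher-student self-distillation pretraining (DINO style) at desk scale.

A student ViT is trained to match the softmaxed, centered and sharpened
outputs of a slowly moving teacher across multiple crops of the same image:
two large "global" crops plus several low-resolution "local" crops. The
teacher sees only global crops; the student sees all crops, and every
(teacher global, student crop) pair with different crop indices contributes
a cross-entropy term. The teacher's parameters are an exponential moving
average of the student's, and its outputs are centered by a running mean to
avoid collapse onto a single output dimension.

The point of running this at toy scale is to give the teacher's CLS
attention input-dependent spatial structure over synthetic phantoms without
any external pretrained weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from ._autodiff import Adam, Tensor
from .vit import AttentionMapSet, ViTConfig, VisionTransformer, build_backbone, extract_cls_attention

__all__ = [
    "DinoConfig",
    "ProjectionHead",
    "multi_crop",
    "dino_loss",
    "ema_update",
    "update_center",
    "pretrain",
    "save_checkpoint",
    "load_checkpoint",
    "PretrainState",
]


@dataclass(frozen=True)
class DinoConfig:
    """Self-distillation hyperparameters.

    Temperatures follow the original self-distillation recipe (student 0.1,
    teacher 0.04 — the sharper teacher provides low-entropy targets); the
    centering momentum 0.9 is likewise the standard value. The teacher EMA
    momentum default of 0.9 is a desk-scale choice: over the few hundred
    optimizer steps of a toy run the teacher must move appreciably toward
    the student, where production-scale schedules start near 0.996.
    """

    n_local_crops: int = 4
    global_scale_range: tuple[float, float] = (0.5, 1.0)
    local_scale_range: tuple[float, float] = (0.1, 0.4)
    global_size: int = 32
    local_size: int = 16
    teacher_momentum: float = 0.9
    student_temperature: float = 0.1
    teacher_temperature: float = 0.04
    center_momentum: float = 0.9
    out_dim: int = 64
    hidden_dim: int = 64
    flip_prob: float = 0.5
    blur_prob: float = 0.5

    def __post_init__(self):
        if self.student_temperature <= 0 or self.teacher_temperature <= 0:
            raise ValueError("temperatures must be positive")
        for m in (self.teacher_momentum, self.center_momentum):
            if not 0.0 <= m <= 1.0:
                raise ValueError("momenta must lie in [0, 1]")
        if self.n_local_crops < 0:
            raise ValueError("n_local_crops must be >= 0")
        if self.local_size >= self.global_size:
            raise ValueError("local crop side must be smaller than global crop side")


class ProjectionHead:
    """3-layer MLP mapping backbone features to the distillation output space."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int, seed: int):
        rng = np.random.default_rng(seed)
        self.params = {
            "w1": Tensor(rng.normal(0, 0.05, (in_dim, hidden_dim)), requires_grad=True),
            "b1": Tensor(np.zeros(hidden_dim), requires_grad=True),
            "w2": Tensor(rng.normal(0, 0.05, (hidden_dim, hidden_dim)), requires_grad=True),
            "b2": Tensor(np.zeros(hidden_dim), requires_grad=True),
            "w3": Tensor(rng.normal(0, 0.05, (hidden_dim, out_dim)), requires_grad=True),
            "b3": Tensor(np.zeros(out_dim), requires_grad=True),
        }

    def forward(self, x: Tensor) -> Tensor:
        h = (x @ self.params["w1"] + self.params["b1"]).gelu()
        h = (h @ self.params["w2"] + self.params["b2"]).gelu()
        return h @ self.params["w3"] + self.params["b3"]

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(arrays[k], dtype=np.float64).copy()

    def set_trainable(self, flag: bool) -> None:
        for p in self.params.values():
            p.requires_grad = flag


def _random_crop_resize(image: np.ndarray, scale_range: tuple[float, float],
                        target: int, rng: np.random.Generator) -> np.ndarray:
    side = image.shape[0]
    frac = rng.uniform(*scale_range)
    crop_side = max(target // 4, int(round(np.sqrt(frac) * side)))
    crop_side = min(crop_side, side)
    top = rng.integers(0, side - crop_side + 1)
    left = rng.integers(0, side - crop_side + 1)
    crop = image[top:top + crop_side, left:left + crop_side]
    if crop_side == target:
        return crop.astype(np.float64).copy()
    return resize(crop, (target, target), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True).astype(np.float64)


def _photometric(crop: np.ndarray, config: DinoConfig,
                 rng: np.random.Generator) -> np.ndarray:
    # grayscale phantoms: horizontal flip + Gaussian blur only
    if rng.random() < config.flip_prob:
        crop = crop[:, ::-1].copy()
    if rng.random() < config.blur_prob:
        crop = gaussian_filter(crop, sigma=rng.uniform(0.1, 1.0))
    return crop


def multi_crop(image: np.ndarray, config: DinoConfig,
               rng: np.random.Generator) -> list[np.ndarray]:
    """Two global crops followed by ``n_local_crops`` local crops.

    Crops are square (area fraction sampled from the configured scale range),
    resized to their target sides, and lightly augmented with random
    horizontal flips and Gaussian blur. An identical generator state
    reproduces the list pixel for pixel.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape[0] < config.global_size:
        raise ValueError("image smaller than the global crop target")
    crops = []
    for _ in range(2):
        c = _random_crop_resize(image, config.global_scale_range, config.global_size, rng)
        crops.append(_photometric(c, config, rng))
    for _ in range(config.n_local_crops):
        c = _random_crop_resize(image, config.local_scale_range, config.local_size, rng)
        crops.append(_photometric(c, config, rng))
    return crops


def dino_loss(student_outputs: list[Tensor], teacher_outputs: list[np.ndarray],
              config: DinoConfig, center: np.ndarray) -> Tensor:
    """Mean cross-entropy between sharpened teacher targets and student
    predictions over all (teacher global g, student crop c) pairs with c != g.

    Teacher targets are softmax((t - center) / teacher_temperature) with
    gradients stopped; student predictions are softmax(s / student_temperature).
    """
    if len(teacher_outputs) != 2:
        raise ValueError("teacher outputs required for exactly the two global crops")
    t_probs = []
    for t in teacher_outputs:
        t = np.asarray(t, dtype=np.float64)
        if t.shape[-1] != center.shape[-1]:
            raise ValueError("teacher output width does not match center width")
        z = (t - center) / config.teacher_temperature
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        t_probs.append(e / e.sum(axis=-1, keepdims=True))
    terms = []
    for g, p_t in enumerate(t_probs):
        for c, s in enumerate(student_outputs):
            if c == g:
                continue
            if s.shape[-1] != center.shape[-1]:
                raise ValueError("student output width does not match center width")
            log_p_s = (s * (1.0 / config.student_temperature)).log_softmax(axis=-1)
            ce = -(Tensor(p_t) * log_p_s).sum(axis=-1).mean()
            terms.append(ce)
    if not terms:
        raise ValueError("no teacher/student pairs to compare")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def ema_update(teacher_params: dict[str, Tensor] | dict[str, np.ndarray],
               student_params: dict[str, Tensor] | dict[str, np.ndarray],
               momentum: float) -> None:
    """teacher <- momentum * teacher + (1 - momentum) * student, elementwise, in place."""
    if not 0.0 <= momentum <= 1.0:
        raise ValueError("momentum must lie in [0, 1]")
    if set(teacher_params) != set(student_params):
        raise ValueError("parameter collections do not match")
    for k in teacher_params:
        t = teacher_params[k]
        s = student_params[k]
        t_arr = t.data if isinstance(t, Tensor) else t
        s_arr = s.data if isinstance(s, Tensor) else s
        if t_arr.shape != s_arr.shape:
            raise ValueError(f"shape mismatch for parameter {k!r}")
        t_arr *= momentum
        t_arr += (1.0 - momentum) * s_arr


def update_center(center: np.ndarray, teacher_batch_outputs: np.ndarray,
                  center_momentum: float) -> np.ndarray:
    """EMA of the teacher's batch-mean output, used to center teacher logits."""
    outputs = np.asarray(teacher_batch_outputs, dtype=np.float64)
    if outputs.shape[-1] != center.shape[-1]:
        raise ValueError("output width does not match center width")
    batch_mean = outputs.reshape(-1, outputs.shape[-1]).mean(axis=0)
    return center_momentum * center + (1.0 - center_momentum) * batch_mean


@dataclass
class PretrainState:
    """Everything needed to resume or reproduce a pretraining run."""

    vit_config: ViTConfig
    dino_config: DinoConfig
    epoch: int
    loss_history: list[float]
    student_backbone: dict[str, np.ndarray]
    student_head: dict[str, np.ndarray]
    teacher_backbone: dict[str, np.ndarray]
    teacher_head: dict[str, np.ndarray]
    best_teacher_backbone: dict[str, np.ndarray]
    best_epoch: int
    center: np.ndarray
    optimizer_state: dict = field(default_factory=dict)
    rng_state: dict = field(default_factory=dict)


def _mean_attention_entropy(backbone: VisionTransformer,
                            images: list[np.ndarray]) -> float:
    from .vit import attention_entropy

    vals = [attention_entropy(extract_cls_attention(backbone, img)) for img in images]
    return float(np.mean(vals))


def pretrain(dataset: list[np.ndarray], vit_config: ViTConfig, dino_config: DinoConfig,
             epochs: int, batch_size: int, seed: int,
             learning_rate: float = 5e-3,
             state: PretrainState | None = None,
             state_callback=None) -> tuple[VisionTransformer, list[float]]:
    """Run the self-distillation loop and return the lowest-loss teacher.

    Each step: multi-crop each image in the batch, forward the student on all
    crops and the teacher on the global crops, take the distillation loss,
    update the student by Adam, the teacher by EMA and the center by its EMA.
    The returned teacher carries the parameters of the epoch with the lowest
    mean loss; the loss history has one finite entry per epoch.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    images = [np.asarray(img, dtype=np.float64) for img in dataset]

    if state is None:
        student = build_backbone(vit_config, seed)
        s_head = ProjectionHead(vit_config.embed_dim, dino_config.hidden_dim,
                                dino_config.out_dim, seed + 1)
        teacher = student.clone()
        t_head = ProjectionHead(vit_config.embed_dim, dino_config.hidden_dim,
                                dino_config.out_dim, seed + 1)
        t_head.load_state_arrays(s_head.state_arrays())
        center = np.zeros(dino_config.out_dim)
        rng = np.random.default_rng(seed + 2)
        loss_history: list[float] = []
        best_loss, best_epoch = np.inf, -1
        best_teacher = teacher.state_arrays()
        start_epoch = 0
        opt = Adam({**student.params,
                    **{f"head.{k}": v for k, v in s_head.params.items()}},
                   lr=learning_rate)
    else:
        student = build_backbone(state.vit_config, seed)
        student.load_state_arrays(state.student_backbone)
        s_head = ProjectionHead(state.vit_config.embed_dim, state.dino_config.hidden_dim,
                                state.dino_config.out_dim, seed + 1)
        s_head.load_state_arrays(state.student_head)
        teacher = build_backbone(state.vit_config, seed)
        teacher.load_state_arrays(state.teacher_backbone)
        t_head = ProjectionHead(state.vit_config.embed_dim, state.dino_config.hidden_dim,
                                state.dino_config.out_dim, seed + 1)
        t_head.load_state_arrays(state.teacher_head)
        center = state.center.copy()
        rng = np.random.default_rng()
        rng.bit_generator.state = state.rng_state
        loss_history = list(state.loss_history)
        best_epoch = state.best_epoch
        best_loss = loss_history[best_epoch] if best_epoch >= 0 else np.inf
        best_teacher = {k: v.copy() for k, v in state.best_teacher_backbone.items()}
        start_epoch = state.epoch
        vit_config, dino_config = state.vit_config, state.dino_config
        opt = Adam({**student.params,
                    **{f"head.{k}": v for k, v in s_head.params.items()}},
                   lr=learning_rate)
        if state.optimizer_state:
            opt.load_state_dict(state.optimizer_state)

    teacher.set_trainable(False)
    t_head.set_trainable(False)
    teacher_params = {**teacher.params, **{f"head.{k}": v for k, v in t_head.params.items()}}
    student_params = {**student.params, **{f"head.{k}": v for k, v in s_head.params.items()}}

    n = len(images)
    for epoch in range(start_epoch, epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            batch_crops = [multi_crop(images[i], dino_config, rng) for i in idx]
            n_crops = 2 + dino_config.n_local_crops
            # group crops of equal size into batched forwards
            student_out: list[Tensor] = []
            for c in range(n_crops):
                arr = np.stack([batch_crops[b][c] for b in range(len(idx))])
                student_out.append(s_head.forward(student.forward(arr)))
            teacher_out: list[np.ndarray] = []
            for c in range(2):
                arr = np.stack([batch_crops[b][c] for b in range(len(idx))])
                teacher_out.append(t_head.forward(teacher.forward(arr)).data)
            loss = dino_loss(student_out, teacher_out, dino_config, center)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite distillation loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ema_update(teacher_params, student_params, dino_config.teacher_momentum)
            center = update_center(center, np.concatenate(teacher_out, axis=0),
                                  dino_config.center_momentum)
            epoch_losses.append(loss.item())
        mean_loss = float(np.mean(epoch_losses))
        loss_history.append(mean_loss)
        if mean_loss < best_loss:
            best_loss = mean_loss
            best_epoch = epoch
            best_teacher = teacher.state_arrays()
        if state_callback is not None:
            state_callback(PretrainState(
                vit_config=vit_config, dino_config=dino_config, epoch=epoch + 1,
                loss_history=list(loss_history),
                student_backbone=student.state_arrays(),
                student_head=s_head.state_arrays(),
                teacher_backbone=teacher.state_arrays(),
                teacher_head=t_head.state_arrays(),
                best_teacher_backbone={k: v.copy() for k, v in best_teacher.items()},
                best_epoch=best_epoch, center=center.copy(),
                optimizer_state=opt.state_dict(),
                rng_state=rng.bit_generator.state))

    best = build_backbone(vit_config, seed)
    best.load_state_arrays(best_teacher)
    return best, loss_history


# -- checkpoint I/O -----------------------------------------------------------

def save_checkpoint(path: str | Path, backbone: VisionTransformer,
                    loss_history: list[float] | None = None,
                    extra: dict | None = None) -> None:
    """Persist a backbone (teacher) checkpoint as an .npz archive."""
    c = backbone.config
    meta = {"vit_config": {"image_size": c.image_size, "patch_size": c.patch_size,
                           "n_heads": c.n_heads, "depth": c.depth,
                           "embed_dim": c.embed_dim},
            "extra": extra or {}}
    arrays = {f"param:{k}": v for k, v in backbone.state_arrays().items()}
    if loss_history is not None:
        arrays["loss_history"] = np.asarray(loss_history, dtype=np.float64)
    np.savez(path, meta=json.dumps(meta, sort_keys=True), **arrays)


def load_checkpoint(path: str | Path) -> tuple[VisionTransformer, list[float]]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        config = ViTConfig(**meta["vit_config"])
        backbone = build_backbone(config, seed=0)
        backbone.load_state_arrays(
            {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")})
        history = list(z["loss_history"]) if "loss_history" in z.files else []
    return backbone, [float(x) for x in history]
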