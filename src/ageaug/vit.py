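"""Small vision-transformer backbone with per-head CLS attention access.

The backbone follows the standard ViT recipe: an image is cut into
non-overlapping square patches (row-major, top-left to bottom-right), each
patch is linearly embedded, a learnable CLS token is prepended, learnable
position embeddings are added, and the sequence runs through pre-norm
transformer blocks. The CLS feature after the final layer norm is the image
representation.

What makes this backbone useful for attention-guided erasing is that every
forward pass records the final block's softmaxed attention weights, so the
CLS-query row of each head can be read out as a spatial saliency map over
the patch grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "ViTConfig",
    "AttentionMapSet",
    "VisionTransformer",
    "build_backbone",
    "extract_cls_attention",
    "upsample_attention",
    "count_active_pixels",
    "is_dense_tissue_candidate",
    "save_attention_maps",
    "load_attention_maps",
    "attention_entropy",
]

DENSE_TISSUE_PIXEL_LIMIT = 50  # heads attending to fewer retained cells than
# this are candidates for dense-tissue localization


@dataclass(frozen=True)
class ViTConfig:
    """Architecture hyperparameters of the square-image ViT backbone."""

    image_size: int = 32
    patch_size: int = 8
    n_heads: int = 6
    depth: int = 2
    embed_dim: int = 48

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}")
        if self.n_heads < 1 or self.depth < 1:
            raise ValueError("n_heads and depth must be >= 1")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}")

    @property
    def grid_side(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid_side ** 2

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads


@dataclass
class AttentionMapSet:
    """Per-head CLS->patch attention grids from one transformer layer.

    ``maps`` has shape (n_heads, grid, grid); heads are addressed 1-based via
    :meth:`head` to match the field convention of numbering attention heads
    from one. When ``normalized`` each head's grid sums to 1 over patch cells.
    """

    maps: np.ndarray
    layer: int
    normalized: bool = True

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3 or self.maps.shape[1] != self.maps.shape[2]:
            raise ValueError("maps must have shape (n_heads, grid, grid)")
        if (self.maps < -1e-12).any():
            raise ValueError("attention maps must be nonnegative")
        if self.normalized:
            sums = self.maps.reshape(self.n_heads, -1).sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("normalized maps must sum to 1 per head")

    @property
    def n_heads(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_side(self) -> int:
        return self.maps.shape[1]

    def head(self, index: int) -> np.ndarray:
        """Return the grid of head ``index`` (1-based)."""
        if not 1 <= index <= self.n_heads:
            raise IndexError(f"head index {index} out of range 1..{self.n_heads}")
        return self.maps[index - 1]


def _bilinear_matrix(src: int, dst: int) -> np.ndarray:
    """(dst^2, src^2) matrix that bilinearly resamples a src x src grid."""
    M = np.zeros((dst * dst, src * src))
    coords = (np.arange(dst) + 0.5) * src / dst - 0.5
    lo = np.clip(np.floor(coords).astype(int), 0, src - 1)
    hi = np.clip(lo + 1, 0, src - 1)
    frac = np.clip(coords - lo, 0.0, 1.0)
    for i in range(dst):
        for j in range(dst):
            for wy, y in ((1 - frac[i], lo[i]), (frac[i], hi[i])):
                for wx, x in ((1 - frac[j], lo[j]), (frac[j], hi[j])):
                    M[i * dst + j, y * src + x] += wy * wx
    return M


class VisionTransformer:
    """Pre-norm ViT over float64 tensors with recorded final-layer attention."""

    def __init__(self, config: ViTConfig, seed: int):
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        c = config

        def param(name: str, shape: tuple[int, ...], scale: float | None = None):
            # Xavier-style scaling keeps activations and input sensitivity O(1)
            # at desk scale, which both the distillation loop and fine-tuning need
            if scale is None:
                scale = (1.0 / shape[0]) ** 0.5
            self.params[name] = Tensor(rng.normal(0.0, scale, size=shape),
                                       requires_grad=True)

        def zeros(name: str, shape: tuple[int, ...]):
            self.params[name] = Tensor(np.zeros(shape), requires_grad=True)

        def ones(name: str, shape: tuple[int, ...]):
            self.params[name] = Tensor(np.ones(shape), requires_grad=True)

        param("patch_embed.w", (c.patch_size ** 2, c.embed_dim))
        zeros("patch_embed.b", (c.embed_dim,))
        param("cls_token", (1, 1, c.embed_dim), scale=0.1)
        param("pos_embed", (1, 1 + c.n_patches, c.embed_dim), scale=0.1)
        for i in range(c.depth):
            ones(f"block{i}.ln1.g", (c.embed_dim,))
            zeros(f"block{i}.ln1.b", (c.embed_dim,))
            param(f"block{i}.qkv.w", (c.embed_dim, 3 * c.embed_dim))
            # query/key projections start small so initial attention is
            # near-uniform, as in standard ViT initialization; the value path
            # keeps full scale so token features stay input-sensitive
            self.params[f"block{i}.qkv.w"].data[:, :2 * c.embed_dim] *= 0.1
            zeros(f"block{i}.qkv.b", (3 * c.embed_dim,))
            param(f"block{i}.proj.w", (c.embed_dim, c.embed_dim))
            zeros(f"block{i}.proj.b", (c.embed_dim,))
            ones(f"block{i}.ln2.g", (c.embed_dim,))
            zeros(f"block{i}.ln2.b", (c.embed_dim,))
            param(f"block{i}.mlp.w1", (c.embed_dim, 4 * c.embed_dim))
            zeros(f"block{i}.mlp.b1", (4 * c.embed_dim,))
            param(f"block{i}.mlp.w2", (4 * c.embed_dim, c.embed_dim))
            zeros(f"block{i}.mlp.b2", (c.embed_dim,))
        ones("ln_f.g", (c.embed_dim,))
        zeros("ln_f.b", (c.embed_dim,))
        self.last_attention: np.ndarray | None = None  # (B, H, T, T) of final block

    # -- parameter plumbing --------------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(arrays[k], dtype=np.float64).copy()

    def clone(self) -> "VisionTransformer":
        twin = VisionTransformer(self.config, seed=0)
        twin.load_state_arrays(self.state_arrays())
        return twin

    def set_trainable(self, flag: bool) -> None:
        for p in self.params.values():
            p.requires_grad = flag

    # -- forward -----------------------------------------------------------

    def _layer_norm(self, x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-6) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + eps) ** -0.5 * g + b

    def _patchify(self, images: np.ndarray) -> np.ndarray:
        b, s, _ = images.shape
        p = self.config.patch_size
        g = s // p
        x = images.reshape(b, g, p, g, p).transpose(0, 1, 3, 2, 4)
        return x.reshape(b, g * g, p * p)

    def forward_tokens(self, images: np.ndarray) -> Tensor:
        """Token sequence (B, 1 + N, D) after the final layer norm.

        Accepts any side divisible by the patch size; position embeddings are
        bilinearly resampled when the patch grid differs from the one the
        backbone was configured with (as with low-resolution local crops).
        """
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        b, s, s2 = images.shape
        if s != s2 or s % self.config.patch_size != 0:
            raise ValueError(
                f"image side {s}x{s2} incompatible with patch size {self.config.patch_size}")
        c = self.config
        g = s // c.patch_size
        patches = self._patchify(images)  # (B, N', p*p)
        x = Tensor(patches) @ self.params["patch_embed.w"] + self.params["patch_embed.b"]
        cls = self.params["cls_token"] + Tensor(np.zeros((b, 1, c.embed_dim)))
        x = concat([cls, x], axis=1)  # (B, 1+N', D)
        pos = self.params["pos_embed"]
        if g != c.grid_side:
            M = Tensor(_bilinear_matrix(c.grid_side, g))
            patch_pos = M @ pos[:, 1:, :]
            pos = concat([pos[:, :1, :], patch_pos], axis=1)
        x = x + pos
        n_tok = 1 + g * g
        for i in range(c.depth):
            h = self._layer_norm(x, self.params[f"block{i}.ln1.g"],
                                 self.params[f"block{i}.ln1.b"])
            qkv = h @ self.params[f"block{i}.qkv.w"] + self.params[f"block{i}.qkv.b"]
            qkv = qkv.reshape(b, n_tok, 3, c.n_heads, c.head_dim)
            qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, H, T, d)
            q, k, v = qkv[0], qkv[1], qkv[2]
            scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(c.head_dim))
            attn = scores.softmax(axis=-1)  # (B, H, T, T)
            if i == c.depth - 1:
                self.last_attention = attn.data.copy()
            out = attn @ v  # (B, H, T, d)
            out = out.transpose(0, 2, 1, 3).reshape(b, n_tok, c.embed_dim)
            x = x + out @ self.params[f"block{i}.proj.w"] + self.params[f"block{i}.proj.b"]
            h2 = self._layer_norm(x, self.params[f"block{i}.ln2.g"],
                                  self.params[f"block{i}.ln2.b"])
            h2 = (h2 @ self.params[f"block{i}.mlp.w1"] + self.params[f"block{i}.mlp.b1"]).gelu()
            x = x + h2 @ self.params[f"block{i}.mlp.w2"] + self.params[f"block{i}.mlp.b2"]
        return self._layer_norm(x, self.params["ln_f.g"], self.params["ln_f.b"])

    def forward(self, images: np.ndarray) -> Tensor:
        """CLS feature (B, D) for a batch of images."""
        return self.forward_tokens(images)[:, 0, :]

    def forward_pooled(self, images: np.ndarray) -> Tensor:
        """CLS feature concatenated with the mean patch-token feature (B, 2D).

        The pooled half keeps the classification head sensitive to local
        structure even while CLS attention is still close to uniform.
        """
        tokens = self.forward_tokens(images)
        cls = tokens[:, 0, :]
        pooled = tokens[:, 1:, :].mean(axis=1)
        return concat([cls, pooled], axis=1)


def build_backbone(config: ViTConfig, seed: int) -> VisionTransformer:
    """Construct a seeded backbone; identical seeds give identical parameters."""
    return VisionTransformer(config, seed)


def extract_cls_attention(backbone: VisionTransformer, image: np.ndarray) -> AttentionMapSet:
    """Final-layer CLS->patch attention of every head for one image.

    The CLS->CLS weight is discarded and each head's remaining weights are
    renormalized to sum to one, then reshaped row-major to the patch grid.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single 2-D image")
    c = backbone.config
    if image.shape != (c.image_size, c.image_size):
        raise ValueError(
            f"image shape {image.shape} does not match configured size {c.image_size}")
    backbone.forward(image[None])
    attn = backbone.last_attention
    if attn is None:
        raise RuntimeError("backbone did not record attention weights")
    cls_to_patch = attn[0, :, 0, 1:]  # (H, N)
    sums = cls_to_patch.sum(axis=1, keepdims=True)
    cls_to_patch = cls_to_patch / sums
    g = c.grid_side
    return AttentionMapSet(maps=cls_to_patch.reshape(c.n_heads, g, g),
                           layer=c.depth - 1, normalized=True)


def upsample_attention(grid: np.ndarray, target_side: int, mode: str = "nearest") -> np.ndarray:
    """Expand a patch-resolution grid to pixel resolution.

    Nearest mode replicates each cell into a square block and requires
    ``target_side`` to be a multiple of the grid side; bilinear mode uses
    smooth resampling (and produces non-piecewise-constant output).
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError("grid must be square 2-D")
    side = grid.shape[0]
    if mode == "nearest":
        if target_side % side != 0:
            raise ValueError(
                f"target_side {target_side} is not a multiple of grid side {side}")
        f = target_side // side
        return np.kron(grid, np.ones((f, f)))
    if mode == "bilinear":
        M = _bilinear_matrix(side, target_side)
        return (M @ grid.reshape(-1)).reshape(target_side, target_side)
    raise ValueError(f"unknown mode {mode!r}")


def count_active_pixels(mask: np.ndarray) -> int:
    """Number of retain-valued cells in a boolean mask."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise TypeError("mask must be boolean")
    return int(mask.sum())


def is_dense_tissue_candidate(mask: np.ndarray,
                              limit: int = DENSE_TISSUE_PIXEL_LIMIT) -> bool:
    """Heads whose mask retains fewer than ``limit`` cells tend to pick out
    small, concentrated structure such as dense breast tissue.

    Whether the count is taken on the patch grid or at pixel resolution is up
    to the caller via the mask's resolution; the patch grid is the
    conventional choice here.
    """
    return count_active_pixels(mask) < limit


def attention_entropy(attention: AttentionMapSet) -> float:
    """Mean Shannon entropy (nats) of the per-head attention distributions."""
    flat = attention.maps.reshape(attention.n_heads, -1)
    p = np.clip(flat, 1e-12, None)
    p = p / p.sum(axis=1, keepdims=True)
    return float(-(p * np.log(p)).sum(axis=1).mean())


def save_attention_maps(attention: AttentionMapSet, path: str | Path,
                        png_dir: str | Path | None = None) -> None:
    """Write one array per head (head_1..head_n) plus optional PNG heatmaps."""
    arrays = {f"head_{i}": attention.head(i) for i in range(1, attention.n_heads + 1)}
    np.savez(path, layer=attention.layer, **arrays)
    if png_dir is not None:
        from PIL import Image

        png_dir = Path(png_dir)
        png_dir.mkdir(parents=True, exist_ok=True)
        for i in range(1, attention.n_heads + 1):
            grid = attention.head(i)
            lo, hi = grid.min(), grid.max()
            scaled = np.zeros_like(grid) if hi == lo else (grid - lo) / (hi - lo)
            Image.fromarray((scaled * 255).astype(np.uint8), mode="L").save(
                png_dir / f"head_{i}.png")


def load_attention_maps(path: str | Path) -> AttentionMapSet:
    with np.load(path) as z:
        layer = int(z["layer"])
        heads = sorted((k for k in z.files if k.startswith("head_")),
                       key=lambda k: int(k.split("_")[1]))
        maps = np.stack([z[k] for k in heads])
    return AttentionMapSet(maps=maps, layer=layer, normalized=True)
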