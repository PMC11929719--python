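"""Attention-guided erasing (AGE) and the random-erasing baseline.

A per-head CLS attention grid is thresholded into a binary retain/erase
mask; during training the mask (upsampled to pixel resolution) erases
everything outside the attended region with a configurable probability P,
leaving only the region of interest visible. Random erasing, the standard
baseline, instead overwrites a random rectangle of random area and aspect
ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .vit import AttentionMapSet, upsample_attention

__all__ = [
    "ThresholdSpec",
    "BinaryMask",
    "ErasingPolicy",
    "REPolicy",
    "attention_to_mask",
    "apply_erasing",
    "age_transform",
    "random_erasing",
    "save_mask_png",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """How an attention grid becomes a binary mask.

    mass_fraction (default): retain the smallest set of highest-attention
    cells holding at least ``value`` of the total attention mass — scale-free
    across heads. quantile: retain cells strictly above the (1 - value)
    empirical quantile. absolute: retain cells >= value.
    """

    strategy: str = "mass_fraction"
    value: float = 0.6

    def __post_init__(self):
        if self.strategy not in ("mass_fraction", "quantile", "absolute"):
            raise ValueError(f"unknown threshold strategy {self.strategy!r}")
        if self.strategy in ("mass_fraction", "quantile"):
            if not 0.0 < self.value <= 1.0:
                raise ValueError(f"{self.strategy} value must lie in (0, 1]")
        elif self.value < 0:
            raise ValueError("absolute level must be nonnegative")


@dataclass
class BinaryMask:
    """Boolean retain/erase map; True marks cells kept by erasing."""

    cells: np.ndarray
    resolution_tag: str = "patch"  # "patch" or "pixel"

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.resolution_tag not in ("patch", "pixel"):
            raise ValueError("resolution_tag must be 'patch' or 'pixel'")
        if not self.cells.any():
            raise ValueError("mask must retain at least one cell")

    def upsample(self, target_side: int) -> "BinaryMask":
        up = upsample_attention(self.cells.astype(np.float64), target_side,
                                mode="nearest") > 0.5
        return BinaryMask(cells=up, resolution_tag="pixel")


@dataclass(frozen=True)
class ErasingPolicy:
    """Configuration of attention-guided erasing for one attention head."""

    head_index: int = 1
    threshold: ThresholdSpec = ThresholdSpec()
    probability: float = 0.6
    fill_value: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if not 0.0 <= self.fill_value <= 1.0:
            raise ValueError("fill_value must lie in [0, 1]")
        if self.head_index < 1:
            raise ValueError("head_index is 1-based")


@dataclass(frozen=True)
class REPolicy:
    """Random-erasing configuration with the standard defaults."""

    probability: float = 0.6
    area_range: tuple[float, float] = (0.02, 0.4)
    aspect_range: tuple[float, float] = (0.3, 1.0 / 0.3)
    fill_mode: str = "random"  # "random" (per-pixel noise) or "constant"
    fill_value: float = 0.0
    max_retries: int = 100

    def __post_init__(self):
        lo, hi = self.area_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("area_range must lie within (0, 1)")
        alo, ahi = self.aspect_range
        if not (0.0 < alo <= ahi):
            raise ValueError("aspect_range must be positive")
        if self.fill_mode not in ("random", "constant"):
            raise ValueError("fill_mode must be 'random' or 'constant'")


def attention_to_mask(grid: np.ndarray, threshold: ThresholdSpec) -> BinaryMask:
    """Threshold a nonnegative attention grid into a patch-resolution mask."""
    grid = np.asarray(grid, dtype=np.float64)
    if (grid < 0).any():
        raise ValueError("attention grid must be nonnegative")
    total = grid.sum()
    if total == 0:
        raise ValueError("all-zero attention grid is degenerate")
    flat = grid.reshape(-1)
    cells = np.zeros(flat.size, dtype=bool)
    if threshold.strategy == "mass_fraction":
        # stable sort on negated values preserves row-major order among ties
        order = np.argsort(-flat, kind="stable")
        csum = np.cumsum(flat[order]) / total
        k = int(np.searchsorted(csum, threshold.value - 1e-12)) + 1
        k = min(k, flat.size)
        cells[order[:k]] = True
    elif threshold.strategy == "quantile":
        level = np.quantile(flat, 1.0 - threshold.value)
        cells = flat > level
        if not cells.any():
            cells[int(np.argmax(flat))] = True
    else:  # absolute
        cells = flat >= threshold.value
        if not cells.any():
            cells[int(np.argmax(flat))] = True
    return BinaryMask(cells=cells.reshape(grid.shape), resolution_tag="patch")


def apply_erasing(image: np.ndarray, mask: BinaryMask | np.ndarray,
                  fill_value: float) -> np.ndarray:
    """Keep pixels under the retain mask, overwrite the rest with the fill."""
    image = np.asarray(image, dtype=np.float64)
    cells = mask.cells if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if cells.shape != image.shape:
        raise ValueError(
            f"mask shape {cells.shape} does not match image shape {image.shape}")
    return np.where(cells, image, float(fill_value))


def age_transform(image: np.ndarray, attention: AttentionMapSet,
                  policy: ErasingPolicy, rng: np.random.Generator) -> np.ndarray:
    """Attention-guided erasing: with probability P, erase everything outside
    the thresholded mask of the selected attention head; otherwise identity."""
    if not 1 <= policy.head_index <= attention.n_heads:
        raise ValueError(
            f"head_index {policy.head_index} out of range 1..{attention.n_heads}")
    image = np.asarray(image, dtype=np.float64)
    if policy.probability == 0.0 or rng.random() >= policy.probability:
        return image.copy()
    mask = attention_to_mask(attention.head(policy.head_index), policy.threshold)
    pixel_mask = mask.upsample(image.shape[0])
    return apply_erasing(image, pixel_mask, policy.fill_value)


def random_erasing(image: np.ndarray, policy: REPolicy,
                   rng: np.random.Generator) -> np.ndarray:
    """Standard random erasing: overwrite one random rectangle with fill."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("image must be nonempty")
    if policy.probability == 0.0 or rng.random() >= policy.probability:
        return image.copy()
    h_img, w_img = image.shape
    area = h_img * w_img
    for _ in range(policy.max_retries):
        target_area = rng.uniform(*policy.area_range) * area
        aspect = rng.uniform(*policy.aspect_range)
        h = int(round(np.sqrt(target_area * aspect)))
        w = int(round(np.sqrt(target_area / aspect)))
        if h < 1 or w < 1 or h > h_img or w > w_img:
            continue
        # integer rounding can push the realized rectangle outside the policy;
        # resample until the final geometry satisfies the configured bounds
        lo, hi = policy.area_range
        alo, ahi = policy.aspect_range
        if lo <= h * w / area <= hi and alo <= h / w <= ahi:
            top = int(rng.integers(0, h_img - h + 1))
            left = int(rng.integers(0, w_img - w + 1))
            out = image.copy()
            if policy.fill_mode == "random":
                out[top:top + h, left:left + w] = rng.random((h, w))
            else:
                out[top:top + h, left:left + w] = policy.fill_value
            return out
    warnings.warn("random_erasing: no feasible rectangle after "
                  f"{policy.max_retries} retries; returning image unchanged")
    return image.copy()


def save_mask_png(mask: BinaryMask, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(mask.cells.astype(np.uint8) * 255, mode="L").convert("1").save(path)
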