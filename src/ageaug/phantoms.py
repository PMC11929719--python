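"""Synthetic mammography-style phantoms with ground-truth ROI masks.

Each phantom is a small grayscale image built from three ingredients:

* a breast-shaped foreground (half-ellipse against a near-black background)
  with mild tissue texture, for the two image-level tasks;
* a class-informative region of interest (ROI) — dense-tissue area for the
  density task, lesion spots for the malignancy/calcification tasks, a
  central blob for the mass task — whose statistics fully determine the
  label;
* class-UNinformative background distractors: bright spots drawn from the
  same intensity range as lesions but with label-independent counts, placed
  outside the ROI. They are what a classifier trained on the full image can
  latch onto spuriously, and what attention-guided erasing removes.

Four tasks mirror the study's structure: ``density`` (4 ordinal classes,
dense-area fraction in disjoint bands), ``malignancy`` (3 classes via lesion
count and brightness), ``calcification_patch`` (3 classes via micro-spot
count/spread) and ``mass_patch`` (3 classes via boundary irregularity of a
central mass).

Everything is bit-exact reproducible from (spec, label, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .vit import AttentionMapSet

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "SplitDataset",
    "TASK_CLASSES",
    "generate_phantom",
    "generate_dataset",
    "fixture_attention_provider",
    "write_dataset",
    "load_dataset",
]

TASK_CLASSES = {
    "density": 4,
    "malignancy": 3,
    "calcification_patch": 3,
    "mass_patch": 3,
}

# dense-area fraction bands (of breast foreground) for density classes A-D;
# disjoint so the ordering is strict for every seed
DENSITY_BANDS = [(0.04, 0.08), (0.13, 0.19), (0.26, 0.36), (0.48, 0.60)]

# per malignancy class: (lesion count range, spot intensity band, disk base
# intensity). The class signal is the lesion count, spread over the whole
# ROI disk, so erasing any part of the ROI corrupts the label; the disk
# itself (base brightness) is class-uninformative and only marks the region
MALIGNANCY_CLASSES = [((2, 3), (0.75, 0.85), 0.45),
                      ((5, 6), (0.75, 0.85), 0.45),
                      ((8, 10), (0.75, 0.85), 0.45)]

# (micro-spot count range, cluster radius range) per calcification class
CALC_CLASSES = [((2, 3), (2.0, 3.0)),
                ((6, 8), (3.5, 4.5)),
                ((12, 15), (5.0, 6.0))]

# boundary perturbation (amplitude, angular frequency) per mass class
MASS_CLASSES = [(0.02, 3), (0.12, 5), (0.28, 9)]


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters shared across one phantom dataset."""

    image_side: int = 32
    task: str = "malignancy"
    roi_intensity_range: tuple[float, float] = (0.50, 0.94)
    background_distractor_level: float = 0.75
    noise_sigma: float = 0.02
    n_distractors_range: tuple[int, int] = (2, 4)
    n_lesions_range: tuple[int, int] = (2, 10)
    roi_radius_range: tuple[float, float] = (5.0, 7.0)

    def __post_init__(self):
        if self.image_side < 16:
            raise ValueError("image_side must be >= 16")
        if self.task not in TASK_CLASSES:
            raise ValueError(f"unknown task {self.task!r}")
        for v in (*self.roi_intensity_range, self.background_distractor_level):
            if not 0.0 <= v <= 1.0:
                raise ValueError("intensities must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return TASK_CLASSES[self.task]


@dataclass
class PhantomSample:
    image: np.ndarray        # (side, side) float in [0, 1]
    roi_mask: np.ndarray     # boolean ground-truth ROI
    label: int
    seed: int
    sample_id: str = ""


@dataclass
class SplitDataset:
    """In-memory stratified dataset with a manifest mirroring the on-disk form."""

    samples: dict[str, PhantomSample]
    manifest: pd.DataFrame   # columns: image_path, label, split
    n_classes: int
    spec: PhantomSpec

    def split(self, name: str) -> list[PhantomSample]:
        ids = self.manifest.loc[self.manifest["split"] == name, "image_path"]
        return [self.samples[i] for i in ids]


def _breast_foreground(side: int) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    cy = side / 2.0
    ax, by = 0.80 * side, 0.42 * side
    return (xx / ax) ** 2 + ((yy - cy) / by) ** 2 <= 1.0


def _disk(side: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _base_image(side: int, foreground: np.ndarray, rng: np.random.Generator,
                base: float = 0.30) -> np.ndarray:
    texture = gaussian_filter(rng.normal(0.0, 1.0, (side, side)), sigma=2.0)
    img = np.full((side, side), 0.02)
    img[foreground] = base + 0.04 * texture[foreground]
    return img


def _add_spot(img: np.ndarray, cy: float, cx: float, radius: float,
              peak: float) -> None:
    side = img.shape[0]
    yy, xx = np.mgrid[0:side, 0:side]
    bump = peak * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * radius ** 2))
    np.maximum(img, bump, out=img)


def _sample_point_in(region: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    ys, xs = np.nonzero(region)
    i = int(rng.integers(0, len(ys)))
    return int(ys[i]), int(xs[i])


def _add_distractors(img: np.ndarray, allowed: np.ndarray, spec: PhantomSpec,
                     rng: np.random.Generator) -> None:
    """Label-independent bright decoy spots in the background tissue.

    Decoys look like lesion spots but their brightness is drawn uniformly
    over the whole lesion range regardless of class, so they carry no label
    information. A model that reads spot brightness off the full image
    absorbs their noise while fitting; erasing them during training yields a
    cleaner estimate of the true ROI cue.
    """
    lo, hi = spec.n_distractors_range
    count = int(rng.integers(lo, hi + 1))
    for _ in range(count):
        if not allowed.any():
            break
        cy, cx = _sample_point_in(allowed, rng)
        peak = rng.uniform(*spec.roi_intensity_range)
        _add_spot(img, cy, cx, rng.uniform(0.8, 1.2), peak)


def _finish(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def _density_phantom(spec: PhantomSpec, label: int, rng: np.random.Generator):
    side = spec.image_side
    fg = _breast_foreground(side)
    img = _base_image(side, fg, rng)
    lo, hi = DENSITY_BANDS[label]
    target_frac = rng.uniform(lo, hi)
    field_ = gaussian_filter(rng.normal(0.0, 1.0, (side, side)), sigma=2.5)
    vals = field_[fg]
    cut = np.quantile(vals, 1.0 - target_frac)
    roi = fg & (field_ > cut)
    if not roi.any():
        roi = fg & (field_ >= vals.max())
    img[roi] += rng.uniform(0.30, 0.40)
    # distractors: a few bright spots anywhere in the non-dense foreground
    _add_distractors(img, fg & ~roi, spec, rng)
    return _finish(img, spec, rng), roi


def _lesion_roi(side: int, fg: np.ndarray, rng: np.random.Generator,
                radius_range=(5.5, 8.5)) -> np.ndarray:
    r = rng.uniform(*radius_range)
    for _ in range(50):
        cy, cx = _sample_point_in(fg, rng)
        disk = _disk(side, cy, cx, r)
        if (disk & ~fg).sum() == 0:
            return disk
    # fallback: deterministic interior disk
    return _disk(side, side / 2.0, side / 3.0, r) & fg


def _malignancy_phantom(spec: PhantomSpec, label: int, rng: np.random.Generator):
    side = spec.image_side
    fg = _breast_foreground(side)
    img = _base_image(side, fg, rng)
    roi = _lesion_roi(side, fg, rng, spec.roi_radius_range)
    # the ROI is a visibly denser disk (an enhancing lesion region) whose base
    # brightness already encodes the class; spots inside it carry the same
    # class band, while look-alike distractor spots on plain tissue carry none
    (cnt_lo, cnt_hi), (int_lo, int_hi), disk_base = MALIGNANCY_CLASSES[label]
    img[roi] = disk_base + 0.03 * rng.standard_normal(int(roi.sum()))
    # spread the lesions over the disk so every part of the ROI carries count
    ys, xs = np.nonzero(roi)
    count = int(rng.integers(cnt_lo, cnt_hi + 1))
    order = rng.permutation(len(ys))[:count]
    for j in order:
        _add_spot(img, int(ys[j]), int(xs[j]), rng.uniform(0.8, 1.1),
                  rng.uniform(int_lo, int_hi))
    _add_distractors(img, fg & ~roi, spec, rng)
    return _finish(img, spec, rng), roi


def _calcification_phantom(spec: PhantomSpec, label: int, rng: np.random.Generator):
    side = spec.image_side
    fg = np.ones((side, side), dtype=bool)  # patch task: tissue fills the patch
    img = 0.30 + 0.05 * gaussian_filter(rng.normal(0.0, 1.0, (side, side)), sigma=1.5)
    (cnt_lo, cnt_hi), (r_lo, r_hi) = CALC_CLASSES[label]
    margin = side // 4
    cy = rng.uniform(margin, side - margin)
    cx = rng.uniform(margin, side - margin)
    cluster_r = rng.uniform(r_lo, r_hi)
    roi = _disk(side, cy, cx, cluster_r + 1.5)
    for _ in range(int(rng.integers(cnt_lo, cnt_hi + 1))):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, cluster_r)
        _add_spot(img, cy + rad * np.sin(ang), cx + rad * np.cos(ang),
                  rng.uniform(0.5, 0.9), rng.uniform(0.80, 0.95))
    _add_distractors(img, ~roi, spec, rng)
    return _finish(img, spec, rng), roi


def _mass_phantom(spec: PhantomSpec, label: int, rng: np.random.Generator):
    side = spec.image_side
    img = 0.25 + 0.04 * gaussian_filter(rng.normal(0.0, 1.0, (side, side)), sigma=1.5)
    amp, freq = MASS_CLASSES[label]
    base_r = 0.30 * side
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:side, 0:side]
    cy = cx = side / 2.0 + rng.uniform(-1.5, 1.5)
    theta = np.arctan2(yy - cy, xx - cx)
    r_bound = base_r * (1.0 + amp * np.sin(freq * theta + phase))
    roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_bound ** 2
    img[roi] += rng.uniform(0.35, 0.45)
    _add_distractors(img, ~roi, spec, rng)
    return _finish(img, spec, rng), roi


_GENERATORS = {
    "density": _density_phantom,
    "malignancy": _malignancy_phantom,
    "calcification_patch": _calcification_phantom,
    "mass_patch": _mass_phantom,
}


def generate_phantom(spec: PhantomSpec, label: int,
                     rng: np.random.Generator | int) -> PhantomSample:
    """Generate one phantom; identical (spec, label, seed) are bit-identical."""
    if not 0 <= label < spec.n_classes:
        raise ValueError(f"label {label} invalid for task {spec.task!r} "
                         f"({spec.n_classes} classes)")
    seed = -1
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    img, roi = _GENERATORS[spec.task](spec, label, rng)
    return PhantomSample(image=img, roi_mask=np.asarray(roi, dtype=bool),
                         label=label, seed=seed)


def generate_dataset(n_per_class: int, spec: PhantomSpec,
                     split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0) -> SplitDataset:
    """Stratified train/val/test phantom dataset.

    Every class appears in every split; the manifest has
    n_per_class * n_classes rows. Per-sample seeds are derived from
    (seed, class, index) so generation is order-independent and bit-exact.
    """
    if n_per_class < 3:
        raise ValueError("need n_per_class >= 3 to stratify into three splits")
    fr = np.asarray(split_fractions, dtype=np.float64)
    if (fr <= 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("split fractions must be positive and sum to 1")
    n_tr = max(1, int(round(fr[0] * n_per_class)))
    n_va = max(1, int(round(fr[1] * n_per_class)))
    while n_tr + n_va > n_per_class - 1:
        if n_tr > 1:
            n_tr -= 1
        else:
            n_va -= 1
    n_te = n_per_class - n_tr - n_va
    samples: dict[str, PhantomSample] = {}
    rows = []
    for cls in range(spec.n_classes):
        for i in range(n_per_class):
            sample_rng = np.random.default_rng([seed, cls, i])
            s = generate_phantom(spec, cls, sample_rng)
            s.seed = seed
            s.sample_id = f"{spec.task}_c{cls}_{i:04d}"
            samples[s.sample_id] = s
            split = ("train" if i < n_tr else
                     "val" if i < n_tr + n_va else "test")
            rows.append({"image_path": s.sample_id, "label": cls, "split": split})
    manifest = pd.DataFrame(rows, columns=["image_path", "label", "split"])
    assert n_te >= 1
    return SplitDataset(samples=samples, manifest=manifest,
                        n_classes=spec.n_classes, spec=spec)


def _roi_cell_overlap(roi_mask: np.ndarray, patch_size: int) -> np.ndarray:
    """Fraction of each patch cell covered by the ROI (grid, row-major)."""
    side = roi_mask.shape[0]
    g = side // patch_size
    cropped = roi_mask[:g * patch_size, :g * patch_size]
    blocks = cropped.reshape(g, patch_size, g, patch_size)
    return blocks.mean(axis=(1, 3))


def fixture_attention_provider(sample: PhantomSample, planted_head: int,
                               n_heads: int, alignment: float,
                               rng: np.random.Generator,
                               patch_size: int = 8) -> AttentionMapSet:
    """Synthetic attention maps with one head planted on the ground-truth ROI.

    The planted head puts at least ``alignment`` of its mass on patch cells
    overlapping the ROI (proportionally to overlap) and spreads the rest
    uniformly; every other head draws near-uniform gamma noise. Used to test
    head selection and erasing without any pretraining.
    """
    if not 1 <= planted_head <= n_heads:
        raise ValueError(f"planted_head {planted_head} out of range 1..{n_heads}")
    if not 0.0 < alignment <= 1.0:
        raise ValueError("alignment must lie in (0, 1]")
    if not sample.roi_mask.any():
        raise ValueError("sample has an empty ROI mask")
    overlap = _roi_cell_overlap(sample.roi_mask, patch_size)
    if overlap.sum() == 0:
        raise ValueError("ROI overlaps no patch cell at this patch size")
    g = overlap.shape[0]
    n_cells = g * g
    maps = np.empty((n_heads, g, g))
    roi_dist = overlap / overlap.sum()
    planted = alignment * roi_dist + (1.0 - alignment) / n_cells
    for h in range(n_heads):
        if h == planted_head - 1:
            maps[h] = planted
        else:
            noise = rng.gamma(shape=25.0, scale=1.0, size=(g, g))
            maps[h] = noise / noise.sum()
    maps /= maps.reshape(n_heads, -1).sum(axis=1)[:, None, None]
    return AttentionMapSet(maps=maps, layer=-1, normalized=True)


def fixture_attention_source(planted_head: int, n_heads: int, alignment: float,
                             seed: int, patch_size: int = 8):
    """Sample -> AttentionMapSet callable wrapping the fixture provider.

    Per-sample noise streams are derived from (seed, crc32(sample_id)) so the
    same source is bit-reproducible across processes.
    """
    import zlib

    def source(sample: PhantomSample) -> AttentionMapSet:
        tag = zlib.crc32(sample.sample_id.encode())
        rng = np.random.default_rng([seed, tag])
        return fixture_attention_provider(sample, planted_head, n_heads,
                                          alignment, rng, patch_size=patch_size)

    return source


# -- on-disk form --------------------------------------------------------------

def write_dataset(dataset: SplitDataset, out_dir: str | Path) -> Path:
    """Write samples as 8-bit PNGs + mask PNGs and the manifest as CSV."""
    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest.copy()
    paths = []
    for sid in manifest["image_path"]:
        s = dataset.samples[sid]
        img8 = np.round(s.image * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out_dir / "images" / f"{sid}.png")
        Image.fromarray(s.roi_mask.astype(np.uint8) * 255, mode="L").save(
            out_dir / "masks" / f"{sid}.png")
        paths.append(f"images/{sid}.png")
    manifest["image_path"] = paths
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_dataset(manifest_path: str | Path, spec: PhantomSpec) -> SplitDataset:
    """Load a written dataset back; 8-bit quantization applies to intensities."""
    from PIL import Image

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    samples: dict[str, PhantomSample] = {}
    ids = []
    for _, row in manifest.iterrows():
        img = np.asarray(Image.open(root / row["image_path"]), dtype=np.float64) / 255.0
        sid = Path(row["image_path"]).stem
        mask_path = root / "masks" / f"{sid}.png"
        mask = (np.asarray(Image.open(mask_path)) > 127) if mask_path.exists() else \
            np.ones_like(img, dtype=bool)
        samples[sid] = PhantomSample(image=img, roi_mask=mask,
                                     label=int(row["label"]), seed=-1, sample_id=sid)
        ids.append(sid)
    manifest = manifest.copy()
    manifest["image_path"] = ids
    return SplitDataset(samples=samples, manifest=manifest,
                        n_classes=int(manifest["label"].max()) + 1, spec=spec)
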