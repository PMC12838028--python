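"""Synthetic segmentation datasets emulating the three benchmark tasks.

Three task families are generated:

* ``multiclass5`` — a blastocyst-like nested-structure task: an outer
  zona-pellucida-like ring (class 1) encloses a trophectoderm-like ring
  (class 2) around a blastocoel-like disk (class 3) that contains an inner
  cell-mass-like blob (class 4), on background 0.
* ``binary_lesion`` / ``binary_polyp`` — one irregular foreground blob
  (class 1) per image, emulating dermoscopic skin-lesion and endoscopic
  polyp masks respectively.

Images render each class at a distinct base intensity (spaced >= 0.15)
with a mild per-class RGB tint and additive Gaussian noise, so small
networks can learn the tasks at desk scale; the generator makes no attempt
at photorealistic texture.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize


@dataclass
class SegmentationSample:
    """One RGB image in [0,1] with an integer label mask."""

    image: np.ndarray  # (H, W, 3) float
    mask: np.ndarray  # (H, W) int
    sample_id: str

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask must share height and width")

    def copy(self) -> "SegmentationSample":
        return SegmentationSample(self.image.copy(), self.mask.copy(), self.sample_id)


# default radius ranges, as fractions of image size
_MULTICLASS_RADII = {
    "zp": (0.36, 0.44),  # outer ring (class 1)
    "te": (0.28, 0.34),  # inner ring (class 2)
    "bl": (0.20, 0.26),  # central disk (class 3)
    "icm": (0.07, 0.11),  # blob inside the disk (class 4)
}
_BINARY_RADII = {
    "binary_lesion": (0.18, 0.30),
    "binary_polyp": (0.14, 0.26),
}

# per-class base gray levels (spacing >= 0.15) and mild RGB tints
_MULTICLASS_BASE = np.array([0.10, 0.30, 0.50, 0.70, 0.90])
_BINARY_BASE = {"binary_lesion": (0.25, 0.65), "binary_polyp": (0.35, 0.80)}
_TINTS = np.array(
    [
        [0.00, 0.00, 0.00],
        [0.03, -0.02, 0.00],
        [-0.02, 0.03, 0.00],
        [0.00, -0.02, 0.03],
        [0.03, 0.00, -0.02],
    ]
)

TASK_KINDS = ("multiclass5", "binary_lesion", "binary_polyp")
AUGMENT_OPS = ("hflip", "vflip", "rotate90", "rgb_shift", "brightness_contrast", "normalize")


@dataclass
class SyntheticTaskSpec:
    task_kind: str
    n_samples: int
    image_size: int = 240
    radii: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind: {self.task_kind!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        defaults = (
            dict(_MULTICLASS_RADII)
            if self.task_kind == "multiclass5"
            else {"blob": _BINARY_RADII[self.task_kind]}
        )
        defaults.update(self.radii)
        self.radii = defaults
        if self.task_kind == "multiclass5":
            order = ["zp", "te", "bl", "icm"]
            for outer, inner in zip(order, order[1:]):
                lo_o = self.radii[outer][0]
                hi_i = self.radii[inner][1]
                if not hi_i < lo_o:
                    raise ValueError(
                        f"radii ranges must nest strictly: max({inner}) < min({outer})"
                    )


def _draw(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    return float(rng.uniform(*lo_hi))


def _multiclass_mask(size: int, rng: np.random.Generator, radii) -> np.ndarray:
    r1 = _draw(rng, radii["zp"]) * size
    r2 = _draw(rng, radii["te"]) * size
    r3 = _draw(rng, radii["bl"]) * size
    r4 = _draw(rng, radii["icm"]) * size
    cy = size / 2 + rng.uniform(-0.02, 0.02) * size
    cx = size / 2 + rng.uniform(-0.02, 0.02) * size
    # ICM blob sits fully inside the BL disk
    max_off = max(r3 - r4, 0.0) * 0.6
    ang = rng.uniform(0, 2 * math.pi)
    off = rng.uniform(0, max_off)
    icm_cy, icm_cx = cy + off * math.sin(ang), cx + off * math.cos(ang)

    yy, xx = np.mgrid[0:size, 0:size]
    d = np.hypot(yy + 0.5 - cy, xx + 0.5 - cx)
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[(d <= r1) & (d > r2)] = 1
    mask[(d <= r2) & (d > r3)] = 2
    mask[d <= r3] = 3
    d_icm = np.hypot(yy + 0.5 - icm_cy, xx + 0.5 - icm_cx)
    mask[d_icm <= r4] = 4
    return mask


def _blob_mask(size: int, rng: np.random.Generator, r_range) -> np.ndarray:
    r0 = _draw(rng, r_range) * size
    cy = size / 2 + rng.uniform(-0.08, 0.08) * size
    cx = size / 2 + rng.uniform(-0.08, 0.08) * size
    n_harm = 4
    amp = rng.uniform(0.0, 0.12, size=n_harm)
    phase = rng.uniform(0, 2 * math.pi, size=n_harm)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy + 0.5 - cy, xx + 0.5 - cx
    theta = np.arctan2(dy, dx)
    radius = r0 * (
        1.0
        + sum(amp[k] * np.cos((k + 2) * theta + phase[k]) for k in range(n_harm))
    )
    return (np.hypot(dy, dx) <= radius).astype(np.uint8)


def _render(mask: np.ndarray, task_kind: str, rng: np.random.Generator, noise_sd: float):
    if task_kind == "multiclass5":
        base, tints = _MULTICLASS_BASE, _TINTS
    else:
        bg, fg = _BINARY_BASE[task_kind]
        base, tints = np.array([bg, fg]), _TINTS[:2]
    img = base[mask][..., None] + tints[mask]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_dataset(spec: SyntheticTaskSpec) -> list[SegmentationSample]:
    """Generate ``spec.n_samples`` reproducible samples for the task."""
    rng = np.random.default_rng(spec.seed)
    samples = []
    for i in range(spec.n_samples):
        if spec.task_kind == "multiclass5":
            mask = _multiclass_mask(spec.image_size, rng, spec.radii)
        else:
            mask = _blob_mask(spec.image_size, rng, spec.radii["blob"])
        image = _render(mask, spec.task_kind, rng, spec.noise_sd)
        samples.append(
            SegmentationSample(image, mask, f"{spec.task_kind}_{spec.seed:03d}_{i:05d}")
        )
    return samples


@dataclass
class ClientPartition:
    """How many samples each client receives, plus a reserved test count."""

    client_counts: list[int]
    test_count: int
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.client_counts) or self.test_count < 0:
            raise ValueError("counts must be non-negative")


def partition_clients(samples, partition: ClientPartition):
    """IID split: a seeded uniform permutation assigns samples to client
    shards and a test shard.  Returns (list_of_shards, test_shard).

    Samples beyond ``sum(client_counts) + test_count`` are left unassigned
    (some published partitions do not account for every sample).
    """
    n = len(samples)
    need = sum(partition.client_counts) + partition.test_count
    if need > n:
        raise ValueError(f"partition needs {need} samples but only {n} are available")
    perm = np.random.default_rng(partition.seed).permutation(n)
    shards, at = [], 0
    for count in partition.client_counts:
        shards.append([samples[j] for j in perm[at : at + count]])
        at += count
    test = [samples[j] for j in perm[at : at + partition.test_count]]
    return shards, test


def train_val_split(shard, train_frac: float = 0.85, seed: int = 0):
    """Seeded shuffle then split; train gets floor(frac*n), at least 1."""
    if not shard:
        raise ValueError("cannot split an empty shard")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    n = len(shard)
    n_train = max(1, int(math.floor(train_frac * n)))
    perm = np.random.default_rng(seed).permutation(n)
    train = [shard[j] for j in perm[:n_train]]
    val = [shard[j] for j in perm[n_train:]]
    return train, val


def augment(
    sample: SegmentationSample,
    ops,
    rng_seed: int = 0,
    rgb_shift_limit: float = 0.05,
    brightness_limit: float = 0.1,
    contrast_limit: float = 0.1,
) -> SegmentationSample:
    """Apply augmentation ops in order.  Geometric ops transform image and
    mask identically (the mask by index permutation, never interpolated);
    photometric ops leave the mask untouched."""
    rng = np.random.default_rng(rng_seed)
    img, mask = sample.image.copy(), sample.mask.copy()
    for op in ops:
        if op == "hflip":
            img, mask = img[:, ::-1].copy(), mask[:, ::-1].copy()
        elif op == "vflip":
            img, mask = img[::-1].copy(), mask[::-1].copy()
        elif op == "rotate90":
            img, mask = np.rot90(img, axes=(0, 1)).copy(), np.rot90(mask).copy()
        elif op == "rgb_shift":
            img = img + rng.uniform(-rgb_shift_limit, rgb_shift_limit, size=3).astype(
                img.dtype
            )
        elif op == "brightness_contrast":
            c = rng.uniform(-contrast_limit, contrast_limit)
            b = rng.uniform(-brightness_limit, brightness_limit)
            img = (img * (1.0 + c) + b).astype(img.dtype)
        elif op == "normalize":
            mu = img.mean(axis=(0, 1), keepdims=True)
            sd = img.std(axis=(0, 1), keepdims=True)
            img = ((img - mu) / np.maximum(sd, 1e-8)).astype(img.dtype)
        else:
            raise ValueError(f"unknown augmentation op: {op!r}")
    return SegmentationSample(img, mask, sample.sample_id)


def resize_sample(sample: SegmentationSample, size: int) -> SegmentationSample:
    """Resize to size x size: bilinear for the image, nearest for the mask."""
    if size < 1:
        raise ValueError("size must be >= 1")
    if sample.image.shape[0] == sample.image.shape[1] == size:
        return sample.copy()
    img = _sk_resize(
        sample.image, (size, size), order=1, anti_aliasing=True, preserve_range=True
    ).astype(sample.image.dtype)
    mask = _sk_resize(
        sample.mask, (size, size), order=0, anti_aliasing=False, preserve_range=True
    ).astype(sample.mask.dtype)
    return SegmentationSample(img, mask, sample.sample_id)


def to_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (N, 3, H, W) images and (N, H, W) masks."""
    images = np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.int64)
    return images, masks
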