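"""Dataset I/O, balanced cropping and the augmentation policy.

Images are RGB arrays ``[3, H, W]`` in [0, 1]; masks are ``[H, W]``
index arrays with class 0 = burn (lesion) and class 1 = non-burn.

The offline augmentation expands each labelled image exactly 20-fold:
five geometric variants (the original plus four random flip/translate/
rotate copies, the mask transformed identically with nearest-neighbour
resampling), each expanded by four photometric variants (one per jitter
type — brightness, contrast, saturation, sharpness — with a factor drawn
from its range; factor 1 is the identity).  Salt-and-pepper noise and a
rectangular pixel mask are then applied in place, emulating device
noise; label masks are never touched by photometric or noise steps.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "LabeledImage", "AugmentPolicy", "load_dataset", "save_dataset",
    "augment_transposition", "augment_jitter", "augment_noise",
    "build_augmented_dataset", "iter_augmented", "crop_and_resize",
    "balanced_windows",
]


@dataclass
class LabeledImage:
    image: np.ndarray  # [3, H, W] float in [0, 1]
    mask: np.ndarray   # [H, W] uint8 in {0, 1}
    id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError(f"image must be [3, H, W], got {self.image.shape}")
        if self.mask.shape != self.image.shape[1:]:
            raise ValueError(
                f"mask shape {self.mask.shape} != image spatial {self.image.shape[1:]}")
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise ValueError(f"mask of {self.id!r} is not binary")
        self.mask = self.mask.astype(np.uint8)


@dataclass
class AugmentPolicy:
    """Offline ×20 augmentation: 5 geometric × 4 photometric variants."""

    flip_prob: float = 0.5
    translate_range: int = 100          # pixels, each axis, both signs
    rotate_range: float = 90.0          # degrees, both signs
    transposition_copies: int = 5       # original + 4 randomised
    jitter_copies: int = 4              # one per jitter type
    brightness: tuple = (0.5, 1.5)
    contrast: tuple = (0.5, 1.5)
    saturation: tuple = (0.0, 2.0)
    sharpness: tuple = (0.0, 2.0)
    salt_pepper_prob: float = 0.01
    mask_prob: float = 0.5              # chance of zeroing one square patch
    mask_patch: int = 16
    seed: int = 0

    @property
    def multiplier(self) -> int:
        return self.transposition_copies * self.jitter_copies


# ---------------------------------------------------------------------------
# I/O

_IMG_EXT = (".png", ".jpg", ".jpeg")


def load_dataset(directory) -> list[LabeledImage]:
    """Load paired ``images/*`` and ``masks/<id>.png`` files."""
    directory = Path(directory)
    img_dir, mask_dir = directory / "images", directory / "masks"
    items: list[LabeledImage] = []
    if not img_dir.is_dir():
        return items
    for img_path in sorted(img_dir.iterdir()):
        if img_path.suffix.lower() not in _IMG_EXT:
            continue
        mask_path = mask_dir / (img_path.stem + ".png")
        if not mask_path.exists():
            raise FileNotFoundError(f"no mask for image {img_path.name}")
        image = np.asarray(Image.open(img_path).convert("RGB"), dtype=np.float64) / 255.0
        mask = np.asarray(Image.open(mask_path))
        if mask.ndim == 3:
            mask = mask[..., 0]
        bad = np.setdiff1d(np.unique(mask), [0, 1])
        if bad.size:
            raise ValueError(
                f"mask {mask_path.name} contains non-binary values {bad.tolist()}")
        items.append(LabeledImage(image=image.transpose(2, 0, 1), mask=mask,
                                  id=img_path.stem))
    return items


def save_dataset(items, directory, split=None) -> None:
    """Write the standard layout: images/, masks/ and a manifest CSV."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for item in items:
        arr = np.clip(item.image, 0, 1).transpose(1, 2, 0)
        Image.fromarray((arr * 255).round().astype(np.uint8)).save(
            directory / "images" / f"{item.id}.png")
        Image.fromarray(item.mask.astype(np.uint8), mode="L").save(
            directory / "masks" / f"{item.id}.png")
        rows.append((item.id, (split or {}).get(item.id, "train")))
    with open(directory / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "split"])
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# geometric augmentation


def _transpose_one(item: LabeledImage, policy: AugmentPolicy,
                   rng: np.random.Generator, tag: str) -> LabeledImage:
    img, mask = item.image, item.mask.astype(np.float64)
    if rng.random() < policy.flip_prob:
        img, mask = img[:, :, ::-1], mask[:, ::-1]
    if rng.random() < policy.flip_prob:
        img, mask = img[:, ::-1, :], mask[::-1, :]
    angle = rng.uniform(-policy.rotate_range, policy.rotate_range)
    dy = rng.integers(-policy.translate_range, policy.translate_range + 1)
    dx = rng.integers(-policy.translate_range, policy.translate_range + 1)
    img = ndimage.rotate(img, angle, axes=(2, 1), reshape=False, order=1,
                         mode="constant", cval=0.0)
    mask = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False, order=0,
                          mode="constant", cval=1.0)
    img = ndimage.shift(img, (0, dy, dx), order=1, mode="constant", cval=0.0)
    mask = ndimage.shift(mask, (dy, dx), order=0, mode="constant", cval=1.0)
    return LabeledImage(image=np.clip(img, 0, 1),
                        mask=(mask > 0.5).astype(np.uint8),
                        id=f"{item.id}_{tag}")


def augment_transposition(item: LabeledImage, policy: AugmentPolicy,
                          rng: np.random.Generator) -> list[LabeledImage]:
    """The original plus four random flip/translate/rotate copies.

    The mask is transformed with nearest-neighbour resampling (binary
    preserved); regions translated or rotated in from outside the frame
    are background: image 0, mask class 1 (non-burn).
    """
    out = [LabeledImage(image=item.image.copy(), mask=item.mask.copy(),
                        id=f"{item.id}_t0")]
    for i in range(1, policy.transposition_copies):
        out.append(_transpose_one(item, policy, rng, f"t{i}"))
    return out


# ---------------------------------------------------------------------------
# photometric augmentation (factor 1 = identity for every jitter type)


def _luminance(img: np.ndarray) -> np.ndarray:
    return 0.299 * img[0] + 0.587 * img[1] + 0.114 * img[2]


def _jitter(img: np.ndarray, kind: str, factor: float) -> np.ndarray:
    if kind == "brightness":
        out = img * factor
    elif kind == "contrast":
        mean = _luminance(img).mean()
        out = mean + factor * (img - mean)
    elif kind == "saturation":
        gray = _luminance(img)[None]
        out = gray + factor * (img - gray)
    elif kind == "sharpness":
        smooth = ndimage.uniform_filter(img, size=(1, 3, 3), mode="nearest")
        out = smooth + factor * (img - smooth)
    else:
        raise ValueError(f"unknown jitter kind {kind!r}")
    return np.clip(out, 0.0, 1.0)


_JITTER_KINDS = ("brightness", "contrast", "saturation", "sharpness")


def augment_jitter(item: LabeledImage, policy: AugmentPolicy,
                   rng: np.random.Generator,
                   factors: dict | None = None) -> list[LabeledImage]:
    """Four copies, one per jitter type, each with a factor from its range."""
    out = []
    for kind in _JITTER_KINDS[: policy.jitter_copies]:
        lo, hi = getattr(policy, kind)
        f = factors[kind] if factors else rng.uniform(lo, hi)
        out.append(LabeledImage(image=_jitter(item.image, kind, f),
                                mask=item.mask.copy(),
                                id=f"{item.id}_{kind}"))
    return out


def augment_noise(item: LabeledImage, policy: AugmentPolicy,
                  rng: np.random.Generator) -> LabeledImage:
    """Salt-and-pepper noise plus an optional zeroed rectangular patch."""
    img = item.image.copy()
    H, W = img.shape[1:]
    u = rng.random((H, W))
    img[:, u < policy.salt_pepper_prob / 2] = 0.0
    img[:, (u >= policy.salt_pepper_prob / 2) & (u < policy.salt_pepper_prob)] = 1.0
    if policy.mask_prob > 0 and rng.random() < policy.mask_prob:
        ph = min(policy.mask_patch, H)
        pw = min(policy.mask_patch, W)
        y = int(rng.integers(0, H - ph + 1))
        x = int(rng.integers(0, W - pw + 1))
        img[:, y:y + ph, x:x + pw] = 0.0
    return LabeledImage(image=img, mask=item.mask.copy(), id=item.id)


def iter_augmented(items, policy: AugmentPolicy):
    """Lazily yield the ×20 offline augmentation of ``items``."""
    rng = np.random.default_rng(policy.seed)
    for item in items:
        for t_item in augment_transposition(item, policy, rng):
            for j_item in augment_jitter(t_item, policy, rng):
                yield augment_noise(j_item, policy, rng)


def build_augmented_dataset(items, policy: AugmentPolicy) -> list[LabeledImage]:
    """Offline augmentation: |output| = 20 × |input|, deterministic in the seed."""
    return list(iter_augmented(items, policy))


# ---------------------------------------------------------------------------
# cropping


def _resize_item(image: np.ndarray, mask: np.ndarray, target: int):
    pil_img = Image.fromarray(
        (np.clip(image, 0, 1).transpose(1, 2, 0) * 255).round().astype(np.uint8))
    pil_img = pil_img.resize((target, target), Image.BILINEAR)
    pil_mask = Image.fromarray(mask.astype(np.uint8), mode="L").resize(
        (target, target), Image.NEAREST)
    return (np.asarray(pil_img, dtype=np.float64).transpose(2, 0, 1) / 255.0,
            np.asarray(pil_mask))


def balanced_windows(mask: np.ndarray, crop_size: int,
                     stride: int | None = None) -> list[tuple[int, int]]:
    """Greedy disjoint crop windows balancing the two class shares.

    Candidate top-left corners on a stride grid are scored by
    min(class-0 share, class-1 share) and selected greedily under a
    no-overlap constraint; if no window contains both classes, a regular
    non-overlapping grid is returned instead.
    """
    H, W = mask.shape
    stride = stride or max(1, crop_size // 4)
    padded = np.zeros((H + 1, W + 1))
    padded[1:, 1:] = np.cumsum(np.cumsum(mask == 0, axis=0), axis=1)

    def zero_count(y, x):
        return (padded[y + crop_size, x + crop_size] - padded[y, x + crop_size]
                - padded[y + crop_size, x] + padded[y, x])

    area = crop_size * crop_size
    scored = []
    for y in range(0, H - crop_size + 1, stride):
        for x in range(0, W - crop_size + 1, stride):
            share0 = zero_count(y, x) / area
            scored.append((min(share0, 1 - share0), y, x))
    scored.sort(reverse=True)

    chosen: list[tuple[int, int]] = []
    if scored and scored[0][0] > 0:
        for score, y, x in scored:
            if score <= 0:
                break
            if all(abs(y - cy) >= crop_size or abs(x - cx) >= crop_size
                   for cy, cx in chosen):
                chosen.append((y, x))
    if not chosen:  # single-class image: regular grid fallback
        chosen = [(y, x) for y in range(0, H - crop_size + 1, crop_size)
                  for x in range(0, W - crop_size + 1, crop_size)]
    return chosen


def crop_and_resize(item: LabeledImage, target: int = 256,
                    crop_size: int | None = None) -> list[LabeledImage]:
    """Disjoint class-balanced crops, each resized to ``target``×``target``.

    Images not larger than one crop are resized whole.
    """
    H, W = item.mask.shape
    if crop_size is None:
        crop_size = max(target, min(H, W) // 2)
    if H <= crop_size or W <= crop_size:
        img, mask = _resize_item(item.image, item.mask, target)
        return [LabeledImage(image=img, mask=mask, id=f"{item.id}_c0")]

    out = []
    for i, (y, x) in enumerate(balanced_windows(item.mask, crop_size)):
        img = item.image[:, y:y + crop_size, x:x + crop_size]
        mask = item.mask[y:y + crop_size, x:x + crop_size]
        rimg, rmask = _resize_item(img, mask, target)
        out.append(LabeledImage(image=rimg, mask=rmask, id=f"{item.id}_c{i}"))
    return out
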